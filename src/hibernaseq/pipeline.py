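"""End-to-end pipeline orchestration and supplementary-table validation.

Stages run in study order — simulate, demultiplex, trim, remove artificial
replicates, assemble, annotate, quantify, normalize, exact-test, density
report — each consuming only prior outputs, with a manifest recording
parameters, per-stage read counts, output checksums and wall time so that
identical configuration and seed reproduce identical results.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, assembly, density, destats, quantify, reads as readmod, simulate

__all__ = [
    "RunConfig",
    "RunManifest",
    "run",
    "validate_against_supplementary",
    "published_normalized_counts",
    "reported_fold_changes",
]


@dataclass
class RunConfig:
    output_dir: str = "hibernaseq_run"
    seed: int = 0
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    trim_policy: readmod.TrimPolicy = field(default_factory=readmod.TrimPolicy)
    replicate_policy: readmod.ReplicateFilterPolicy = field(default_factory=readmod.ReplicateFilterPolicy)
    assembly_params: assembly.AssemblyParams = field(default_factory=assembly.AssemblyParams)
    evalue_cutoff: float = 1e-5
    fdr_cutoff: float = destats.FDR_CUTOFF
    assemble_mito: bool = True
    run_de: bool = True
    density_genes: int = 3  # mito units to profile in the density report

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = simulate.SimulationConfig(**raw.pop("simulation", {}))
        trim_p = readmod.TrimPolicy(**raw.pop("trim_policy", {}))
        rep_p = readmod.ReplicateFilterPolicy(**raw.pop("replicate_policy", {}))
        asm_p = assembly.AssemblyParams(**raw.pop("assembly_params", {}))
        return cls(simulation=sim, trim_policy=trim_p, replicate_policy=rep_p,
                   assembly_params=asm_p, **raw)


@dataclass
class RunManifest:
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, name: str, started: float, counts: dict, outputs: dict[str, str]) -> None:
        self.stages[name] = {
            "wall_seconds": round(time.time() - started, 3),
            "counts": counts,
            "outputs": outputs,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh, indent=1, default=str)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    # newline-normalize so checksums are platform-stable
    h.update(path.read_bytes().replace(b"\r\n", b"\n"))
    return h.hexdigest()


def run(config: RunConfig) -> RunManifest:
    """Execute the full synthetic pipeline; returns the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)

    def finish(stage: str, started: float, counts: dict, paths: list[Path]) -> None:
        manifest.record(stage, started, counts, {p.name: _checksum(p) for p in paths})

    # --- simulate -----------------------------------------------------
    t0 = time.time()
    truth, raw_reads = simulate.generate_run(config.simulation)
    reads_fq = out / "reads.fastq"
    ref_fa = out / "reference.fasta"
    gene_map = out / "gene_map.tsv"
    design_tsv = out / "design.tsv"
    truth_json = out / "ground_truth.json"
    simulate.write_fastq(raw_reads, reads_fq)
    simulate.write_reference_fasta(truth, ref_fa)
    simulate.write_gene_map(truth, gene_map)
    simulate.write_design(truth, design_tsv)
    simulate.write_ground_truth_json(truth, truth_json)
    finish("simulate", t0, {"reads": len(raw_reads), "genes": len(truth.transcripts)},
           [reads_fq, ref_fa, gene_map, design_tsv, truth_json])

    # --- demultiplex --------------------------------------------------
    t0 = time.time()
    table = readmod.DemuxTable.from_design(truth.design)
    bins = readmod.demultiplex(raw_reads, table)
    unmatched = len(bins.pop("__unmatched__"))
    finish("demultiplex", t0,
           {"samples": len(bins), "unmatched": unmatched,
            "assigned": sum(len(v) for v in bins.values())}, [])

    # --- trim ---------------------------------------------------------
    t0 = time.time()
    trimmed: dict[str, list] = {}
    discarded = 0
    for sample, rs in bins.items():
        trimmed[sample], rep = readmod.trim(rs, config.trim_policy)
        discarded += rep.discarded
    finish("trim", t0, {"discarded": discarded,
                        "kept": sum(len(v) for v in trimmed.values())}, [])

    # --- remove artificial replicates ---------------------------------
    t0 = time.time()
    filtered, removal = readmod.remove_artificial_replicates(
        trimmed, config.replicate_policy, truth.design)
    removal_tsv = out / "replicate_removal.tsv"
    removal.to_frame().to_csv(removal_tsv, sep="\t")
    finish("dedup", t0, {"removed": removal.total_removed}, [removal_tsv])

    flat = [r for rs in filtered.values() for r in rs]

    # --- assemble -----------------------------------------------------
    contigs = []
    if config.assemble_mito:
        t0 = time.time()
        contigs = assembly.assemble(flat, config.assembly_params)
        contigs_fa = out / "contigs.fasta"
        assembly.write_contigs_fasta(contigs, contigs_fa)
        outputs = [contigs_fa]
        counts = {"contigs": len(contigs),
                  "singletons": sum(1 for c in contigs if c.is_singleton)}
        mito_genes = {g: truth.transcripts[g] for g in truth.mito_genes}
        try:
            mito = assembly.reconstruct_mito(contigs, truth.mito_genes, mito_genes,
                                             config.assembly_params)
            mito_fa = out / "mito_genome.fasta"
            mito_gff = out / "mito_genome.gff3"
            with open(mito_fa, "w") as fh:
                topo = "circular" if mito.circular else "linear"
                fh.write(f">mito topology={topo} length={mito.length}\n{mito.sequence}\n")
            assembly.write_mito_gff3(mito, mito_gff)
            counts.update({"mito_length": mito.length, "mito_circular": int(mito.circular),
                           "mito_gaps": len(mito.gaps)})
            outputs += [mito_fa, mito_gff]
        except ValueError:
            counts["mito_length"] = 0
        finish("assemble", t0, counts, outputs)

    # --- annotate -----------------------------------------------------
    t0 = time.time()
    index = annotation.build_index(truth.transcripts, {g: g for g in truth.transcripts})
    assignments = annotation.assign_reads(flat, index, config.evalue_cutoff)
    ident = annotation.summarize_identification(assignments, set(truth.mito_genes))
    ident_tsv = out / "identification_summary.tsv"
    ident.to_csv(ident_tsv, sep="\t")
    finish("annotate", t0,
           {"reads": len(assignments),
            "identified": int(sum(1 for a in assignments if a.gene))}, [ident_tsv])

    # --- quantify -----------------------------------------------------
    t0 = time.time()
    matrix, unmatched_counts = quantify.count_reads(
        [(a.sample, a.gene) for a in assignments], truth.design[["tissue", "timepoint"]])
    counts_tsv = out / "counts.tsv"
    matrix.to_tsv(counts_tsv)
    finish("quantify", t0, {"genes": len(matrix.genes),
                            "unmatched": int(unmatched_counts.sum())}, [counts_tsv])

    # --- normalize + differential expression --------------------------
    de_paths: list[Path] = []
    if config.run_de:
        t0 = time.time()
        de_counts = {}
        for tissue in sorted(matrix.samples["tissue"].unique()):
            sub = matrix.subset_tissue(tissue)
            normalized, factors = quantify.upper_quartile_normalize(sub, tissue)
            norm_tsv = out / f"normalized_{tissue}.tsv"
            factors_tsv = out / f"normalization_factors_{tissue}.tsv"
            normalized.to_tsv(norm_tsv)
            factors.to_frame().to_csv(factors_tsv, sep="\t")
            results, summary = destats.de_gene_list(sub, cutoff=config.fdr_cutoff)
            de_tsv = out / f"de_results_{tissue}.tsv"
            destats.results_table(results).to_csv(de_tsv, sep="\t", index=False)
            de_counts[tissue] = summary.n_pass
            de_paths += [norm_tsv, factors_tsv, de_tsv]
        finish("detest", t0, {"passing_genes": de_counts}, de_paths)

    # --- density report -----------------------------------------------
    t0 = time.time()
    lengths = density.LengthDistribution.from_lengths(
        [truth.read_origins[r.id][2] for r in flat])
    profiles = []
    for gene in truth.mito_genes[: config.density_genes]:
        placements = [(s, s + ln - 1) for rid, (g, s, ln) in truth.read_origins.items()
                      if g == gene]
        if not placements:
            continue
        prof = density.coverage_report(gene, len(truth.transcripts[gene]), placements, lengths)
        profiles.append(prof)
    density_tsv = out / "density_r2.tsv"
    pd.DataFrame(
        [{"gene": p.name, "length": p.length, "r2": p.r2,
          "missing_reason": p.r2_missing_reason} for p in profiles]
    ).to_csv(density_tsv, sep="\t", index=False)
    finish("density", t0, {"profiles": len(profiles)}, [density_tsv])

    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    return manifest


# --- supplementary-table validation ----------------------------------


def published_normalized_counts() -> pd.DataFrame:
    """The normalized-count rows printed in the study (MALAT1 and the two
    ACOD paralogs), as an S1-style table."""
    with resources.files("hibernaseq.data").joinpath("published_normalized_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reported_fold_changes() -> pd.DataFrame:
    """The fold-change citations printed in the study's results text."""
    with resources.files("hibernaseq.data").joinpath("reported_fold_changes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


S1_COLUMNS = ["gene", "tissue", "April", "August", "October", "Torpor", "IBA", "March"]


def validate_against_supplementary(
    normalized_counts: pd.DataFrame,
    gene_lists: pd.DataFrame | None = None,
    fold_citations: pd.DataFrame | None = None,
    fdr_cutoff: float = destats.FDR_CUTOFF,
) -> dict[str, pd.DataFrame]:
    """Re-derive printed quantities from supplementary-style tables.

    ``normalized_counts`` must carry ``gene``, ``tissue`` and one column per
    time point (the S1 layout).  Fold changes cited in the text are
    recomputed by division and compared to 1 decimal; when ``gene_lists``
    (tissue, n_genes) is given, the FDR-passing gene counts are re-derived
    by running the exact test on the normalized integers and compared.
    Discrepancies are reported, never hidden.
    """
    missing = [c for c in S1_COLUMNS if c not in normalized_counts.columns]
    if missing:
        raise ValueError(f"normalized-count table missing columns {missing}; expected {S1_COLUMNS}")
    if len(normalized_counts) == 0:
        raise ValueError("normalized-count table is empty")
    timepoints = S1_COLUMNS[2:]
    if fold_citations is None:
        fold_citations = reported_fold_changes()

    rows = []
    for _, cite in fold_citations.iterrows():
        sel = normalized_counts[(normalized_counts["gene"] == cite["gene"])
                                & (normalized_counts["tissue"] == cite["tissue"])]
        if sel.empty:
            rows.append({**cite.to_dict(), "recomputed": np.nan, "agrees": None,
                         "note": "gene not in table"})
            continue
        vals = sel.iloc[0]
        num = float(vals[cite["numerator"]])
        if bool(cite.get("lower_bound", 0)) or cite["denominator"] == "all_other":
            others = [float(vals[tp]) for tp in timepoints if tp != cite["numerator"]]
            den = max(others)
            recomputed = num / den if den > 0 else np.inf
            agrees = bool(recomputed >= float(cite["fold"]) - 0.05)
        else:
            den = float(vals[cite["denominator"]])
            recomputed = num / den if den > 0 else np.inf
            agrees = bool(abs(round(recomputed, 1) - float(cite["fold"])) < 0.051)
        rows.append({**cite.to_dict(), "recomputed": round(recomputed, 1), "agrees": agrees,
                     "note": ""})
    fold_report = pd.DataFrame(rows)

    list_report = None
    if gene_lists is not None:
        entries = []
        for _, row in gene_lists.iterrows():
            tissue = row["tissue"]
            sub = normalized_counts[normalized_counts["tissue"] == tissue]
            counts = sub.set_index("gene")[timepoints].astype(np.int64)
            meta = pd.DataFrame({
                "tissue": tissue, "timepoint": timepoints,
                "total_reads": counts.sum(axis=0).to_numpy()}, index=timepoints)
            meta.index = counts.columns
            matrix = quantify.CountMatrix(counts, meta)
            results, summary = destats.de_gene_list(matrix, cutoff=fdr_cutoff)
            entries.append({"tissue": tissue, "published_n": int(row["n_genes"]),
                            "recomputed_n": summary.n_pass,
                            "agrees": summary.n_pass == int(row["n_genes"])})
        list_report = pd.DataFrame(entries)

    out = {"fold_changes": fold_report}
    if list_report is not None:
        out["gene_lists"] = list_report
    return out
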