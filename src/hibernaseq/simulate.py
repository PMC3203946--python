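"""Synthetic 454-style cDNA read sets with known ground truth.

Emulates the structure of a seasonal three-tissue hibernation study: 6 time
points x 3 tissues, single-end reads whose trimmed lengths follow a
truncated Normal(335, 133), a sample-identifying MID barcode plus adaptor
pad prepended to every read (26 bases total, removed by fixed trimming),
a tissue-dependent fraction of reads from a circular mitochondrial genome
whose gene transcripts tile the circle, planted multiplicative fold changes
between time points, and optional emulsion-PCR artificial-replicate
clusters (identical reads injected at a single time point).

Everything is seeded and deterministic; the returned
:class:`GroundTruth` records expected read proportions per sample, every
read's true origin, and the identifiers of injected duplicate copies so
downstream filters, assemblers, annotators and tests can be scored exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "GroundTruth",
    "Read",
    "ConfigurationError",
    "generate_reference",
    "fragment_and_sample_reads",
    "inject_artificial_replicates",
    "generate_run",
    "sample_count_matrix",
]

TIMEPOINTS = ("April", "August", "October", "Torpor", "IBA", "March")
TISSUES = ("heart", "skeletal_muscle", "wat")

#: study-like fraction of reads of mitochondrial origin per tissue
DEFAULT_MITO_FRACTION = {"heart": 0.21, "skeletal_muscle": 0.10, "wat": 0.02}

#: mitochondrial transcript units in standard vertebrate order with nominal
#: length weights; ATP8/ATP6 are the designated overlapping pair
MITO_GENE_WEIGHTS = [
    ("RNR1", 1000), ("RNR2", 1650), ("NU1M", 1000), ("NU2M", 1080),
    ("COX1", 1600), ("COX2", 710), ("ATP8", 210), ("ATP6", 700),
    ("COX3", 810), ("NU3M", 370), ("NU4LM", 310), ("NU4M", 1430),
    ("NU5M", 1880), ("NU6M", 550), ("CYB", 1159),
]
MITO_OVERLAP_PAIR = ("ATP8", "ATP6")
MITO_OVERLAP_BASES = 40


class ConfigurationError(ValueError):
    """A SimulationConfig field violates its invariants."""


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative expression change for one gene in one sample."""

    gene: str
    tissue: str
    timepoint: str
    fold: float


@dataclass
class Read:
    """One sequenced cDNA fragment."""

    id: str
    sequence: str
    quality: str | None = None
    sample: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_tissues: int = 3
    n_timepoints: int = 6
    n_genes: int = 300
    reads_per_sample: int = 2000
    transcript_length_range: tuple[int, int] = (600, 3000)
    read_length_mean: float = 335.0
    read_length_sd: float = 133.0
    min_read_length: int = 40
    mid_length: int = 10
    adaptor_pad: int = 16  # MID + pad = the 26 bases removed by trimming
    duplicate_rate: float = 0.0
    duplicate_cluster_size: int = 4
    planted_effects: tuple[PlantedEffect, ...] = ()
    mito_fraction: dict[str, float] | None = None
    mito_length: int = 16459
    junction_read_fraction: float = 0.05  # of mito reads: unprocessed polycistronic fragments
    error_rate: float = 0.0
    abundance_sigma: float = 1.0  # log-normal spread of baseline gene abundances

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not 1 <= self.n_tissues <= len(TISSUES):
            raise ConfigurationError(f"n_tissues must be in 1..{len(TISSUES)}")
        if not 2 <= self.n_timepoints <= len(TIMEPOINTS):
            raise ConfigurationError(f"n_timepoints must be in 2..{len(TIMEPOINTS)}")
        if self.read_length_mean <= 26 + self.mid_length:
            raise ConfigurationError("read_length_mean must exceed 26 + mid_length")
        if self.read_length_sd <= 0:
            raise ConfigurationError("read_length_sd must be > 0")
        if self.min_read_length < 1:
            raise ConfigurationError("min_read_length must be >= 1")
        if self.transcript_length_range[0] < self.min_read_length:
            raise ConfigurationError("transcript_length_range lower bound below min_read_length")
        if self.transcript_length_range[0] > self.transcript_length_range[1]:
            raise ConfigurationError("transcript_length_range must be (low, high) with low <= high")
        if not 0 <= self.duplicate_rate <= 1:
            raise ConfigurationError("duplicate_rate must be in [0, 1]")
        if self.duplicate_cluster_size < 3:
            raise ConfigurationError("duplicate_cluster_size must be >= 3")
        for eff in self.planted_effects:
            if eff.fold <= 0:
                raise ConfigurationError(f"planted fold for {eff.gene} must be > 0")
            if eff.timepoint not in TIMEPOINTS[: self.n_timepoints]:
                raise ConfigurationError(f"planted timepoint {eff.timepoint!r} not in design")
            if eff.tissue not in TISSUES[: self.n_tissues]:
                raise ConfigurationError(f"planted tissue {eff.tissue!r} not in design")
        for tissue, frac in (self.mito_fraction or {}).items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"mito_fraction[{tissue!r}] must be in [0, 1]")
        if not 0 <= self.junction_read_fraction <= 1:
            raise ConfigurationError("junction_read_fraction must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ConfigurationError("error_rate must be in [0, 1)")

    @property
    def tissues(self) -> tuple[str, ...]:
        return TISSUES[: self.n_tissues]

    @property
    def timepoints(self) -> tuple[str, ...]:
        return TIMEPOINTS[: self.n_timepoints]

    def mito_fraction_for(self, tissue: str) -> float:
        table = self.mito_fraction if self.mito_fraction is not None else DEFAULT_MITO_FRACTION
        return float(table.get(tissue, 0.0))


@dataclass
class GroundTruth:
    transcripts: dict[str, str]  # gene -> sequence (nuclear and mito units)
    mito_genome: str
    mito_intervals: list[tuple[str, int, int, str]]  # (gene, start, end, strand), 1-based inclusive circular
    design: pd.DataFrame  # index sample id; columns tissue, timepoint, mid
    adaptor_pad_sequence: str
    expected_read_proportions: pd.DataFrame  # genes x samples, read-level, sums to 1
    injected_duplicate_read_ids: set[str] = field(default_factory=set)
    read_origins: dict[str, tuple[str, int, int]] = field(default_factory=dict)  # read id -> (gene, start1, length)

    @property
    def mito_genes(self) -> list[str]:
        return [name for name, *_ in self.mito_intervals]

    @property
    def nuclear_genes(self) -> list[str]:
        mito = set(self.mito_genes)
        return [g for g in self.transcripts if g not in mito]


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _make_mids(rng: np.random.Generator, count: int, length: int, min_dist: int = 3) -> list[str]:
    mids: list[str] = []
    while len(mids) < count:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, m)) >= min_dist for m in mids):
            mids.append(cand)
    return mids


def _mito_layout(total_length: int) -> list[tuple[str, int, int, str]]:
    """Tile the circle with the gene units, one designated overlap pair."""
    names = [n for n, _ in MITO_GENE_WEIGHTS]
    weights = np.array([w for _, w in MITO_GENE_WEIGHTS], dtype=float)
    span = total_length + MITO_OVERLAP_BASES  # gene spans sum to genome + overlap
    lengths = np.floor(weights / weights.sum() * span).astype(int)
    lengths[-1] += span - int(lengths.sum())  # absorb rounding in the last unit
    intervals = []
    pos = 1
    for name, ln in zip(names, lengths):
        if name == MITO_OVERLAP_PAIR[1]:
            pos -= MITO_OVERLAP_BASES  # ATP6 starts inside ATP8
        start, end = pos, pos + int(ln) - 1
        intervals.append((name, start, end, "+"))
        pos = end + 1
    assert intervals[-1][2] == total_length
    return intervals


def generate_reference(config: SimulationConfig) -> GroundTruth:
    """Build transcripts, the circular mito genome, the sample design and
    per-sample expected read proportions implementing the planted effects."""
    config.validate()
    rng = _rng(config.seed, "reference")

    lo, hi = config.transcript_length_range
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    transcripts = {g: _random_seq(rng, int(rng.integers(lo, hi + 1))) for g in genes}

    mito_genome = _random_seq(rng, config.mito_length)
    intervals = _mito_layout(config.mito_length)
    for name, start, end, _ in intervals:
        transcripts[name] = mito_genome[start - 1 : end]

    samples = []
    for tissue in config.tissues:
        for tp in config.timepoints:
            samples.append((f"{tissue}_{tp}", tissue, tp))
    mids = _make_mids(rng, len(samples), config.mid_length)
    design = pd.DataFrame(
        {"tissue": [t for _, t, _ in samples], "timepoint": [tp for _, _, tp in samples],
         "mid": mids},
        index=[s for s, _, _ in samples],
    )
    design.index.name = "sample_id"

    # baseline molecule abundances (log-normal), shared across samples
    baseline = np.exp(rng.normal(0.0, config.abundance_sigma, size=config.n_genes))
    mean_j = _trimmed_length_mean(config)
    nuc_lengths = np.array([len(transcripts[g]) for g in genes], dtype=float)
    nuc_eff = np.maximum(nuc_lengths - mean_j + 1, 1.0)  # longer transcripts over-represented
    mito_names = [name for name, *_ in intervals]
    mito_lengths = np.array([len(transcripts[m]) for m in mito_names], dtype=float)
    mito_eff = np.maximum(mito_lengths - mean_j + 1, 1.0)
    mito_weights = mito_eff / mito_eff.sum()

    prop = {}
    for sample_id, tissue, tp in samples:
        weights = baseline.copy()
        for eff in config.planted_effects:
            if eff.tissue == tissue and eff.timepoint == tp:
                try:
                    gi = genes.index(eff.gene)
                except ValueError:
                    raise ConfigurationError(f"planted gene {eff.gene!r} not in reference") from None
                weights[gi] *= eff.fold
        read_w = weights * nuc_eff
        read_w = read_w / read_w.sum()
        frac = config.mito_fraction_for(tissue)
        col = np.concatenate([(1.0 - frac) * read_w, frac * mito_weights])
        prop[sample_id] = col
    proportions = pd.DataFrame(prop, index=genes + mito_names)
    sums = proportions.sum(axis=0)
    assert np.allclose(sums, 1.0, atol=1e-9)

    return GroundTruth(
        transcripts=transcripts,
        mito_genome=mito_genome,
        mito_intervals=intervals,
        design=design,
        adaptor_pad_sequence=_random_seq(rng, config.adaptor_pad),
        expected_read_proportions=proportions,
    )


def _trimmed_length_mean(config: SimulationConfig) -> float:
    a = (config.min_read_length - config.read_length_mean) / config.read_length_sd
    return float(truncnorm.mean(a, np.inf, loc=config.read_length_mean, scale=config.read_length_sd))


def _draw_lengths(rng: np.random.Generator, config: SimulationConfig, size: int) -> np.ndarray:
    a = (config.min_read_length - config.read_length_mean) / config.read_length_sd
    vals = truncnorm.rvs(a, np.inf, loc=config.read_length_mean, scale=config.read_length_sd,
                         size=size, random_state=rng)
    return np.maximum(np.rint(vals).astype(int), config.min_read_length)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def fragment_and_sample_reads(
    truth: GroundTruth,
    config: SimulationConfig,
    sample: str,
    n_reads: int | None = None,
) -> list[Read]:
    """Draw reads for one sample by uniform fragmentation.

    A transcript is chosen by the sample's expected read proportions, a
    trimmed length J from the truncated normal (capped at transcript
    length), and a start uniform over the L-J+1 valid positions; the
    sample's MID plus the adaptor pad is prepended.  A configured fraction
    of mitochondrial reads is drawn instead as unprocessed polycistronic
    fragments: windows of the circular genome that may span unit junctions.
    """
    if sample not in truth.design.index:
        raise KeyError(f"unknown sample {sample!r}")
    if n_reads is None:
        n_reads = config.reads_per_sample
    rng = _rng(config.seed, f"reads:{sample}")
    props = truth.expected_read_proportions[sample]
    gene_names = list(props.index)
    mito = set(truth.mito_genes)
    prefix = truth.design.at[sample, "mid"] + truth.adaptor_pad_sequence
    L_mito = len(truth.mito_genome)
    doubled = truth.mito_genome + truth.mito_genome

    picks = rng.choice(len(gene_names), size=n_reads, p=props.to_numpy())
    lengths = _draw_lengths(rng, config, n_reads)
    reads: list[Read] = []
    for i in range(n_reads):
        gene = gene_names[picks[i]]
        J = int(lengths[i])
        if gene in mito and rng.random() < config.junction_read_fraction:
            # unprocessed fragment of the primary polycistronic transcript
            J = min(J, L_mito)
            start = int(rng.integers(1, L_mito + 1))
            frag = doubled[start - 1 : start - 1 + J]
            origin = ("MT-primary", start, J)
        else:
            seq = truth.transcripts[gene]
            L = len(seq)
            J = min(J, L)
            start = int(rng.integers(1, L - J + 2))
            frag = seq[start - 1 : start - 1 + J]
            origin = (gene, start, J)
        frag = _apply_errors(rng, frag, config.error_rate)
        rid = f"{sample}:r{i:06d}"
        full = prefix + frag
        reads.append(Read(id=rid, sequence=full, quality="?" * len(full)))
        truth.read_origins[rid] = origin
    return reads


def inject_artificial_replicates(
    reads: list[Read], truth: GroundTruth, config: SimulationConfig
) -> list[Read]:
    """Inject emulsion-PCR-style artificial replicate clusters.

    A fraction ``duplicate_rate`` of nuclear genes receives one cluster:
    one existing read of that gene (in one sample, hence one time point) is
    copied ``duplicate_cluster_size - 1`` times, each copy identical in
    sequence with a fresh identifier lexicographically after the original.
    Copy identifiers are recorded in ``truth.injected_duplicate_read_ids``.
    """
    config.validate()
    if config.duplicate_rate == 0:
        return list(reads)
    rng = _rng(config.seed, "duplicates")
    by_gene: dict[str, list[int]] = {}
    for idx, read in enumerate(reads):
        origin = truth.read_origins.get(read.id)
        if origin is not None:
            by_gene.setdefault(origin[0], []).append(idx)
    candidates = sorted(g for g in by_gene if g in set(truth.nuclear_genes))
    n_clusters = int(round(config.duplicate_rate * len(candidates)))
    chosen = rng.choice(len(candidates), size=min(n_clusters, len(candidates)), replace=False)
    out = list(reads)
    for gi in sorted(chosen):
        gene = candidates[gi]
        src = reads[by_gene[gene][int(rng.integers(0, len(by_gene[gene])))]]
        for copy_i in range(1, config.duplicate_cluster_size):
            rid = f"{src.id}_dup{copy_i}"
            out.append(Read(id=rid, sequence=src.sequence, quality=src.quality, sample=src.sample))
            truth.injected_duplicate_read_ids.add(rid)
            truth.read_origins[rid] = truth.read_origins[src.id]
    return out


def generate_run(config: SimulationConfig) -> tuple[GroundTruth, list[Read]]:
    """Reference + all samples' reads + duplicate injection, in one call."""
    truth = generate_reference(config)
    reads: list[Read] = []
    for sample in truth.design.index:
        reads.extend(fragment_and_sample_reads(truth, config, sample))
    reads = inject_artificial_replicates(reads, truth, config)
    return truth, reads


def sample_count_matrix(truth: GroundTruth, config: SimulationConfig, total_reads: int,
                        tissue: str | None = None):
    """Multinomial gene x sample counts drawn directly from the expected
    read proportions (no read-level simulation) — the count structure the
    differential-expression stage sees, at arbitrary depth."""
    from .quantify import CountMatrix

    rng = _rng(config.seed, f"counts:{tissue or 'all'}")
    design = truth.design if tissue is None else truth.design[truth.design["tissue"] == tissue]
    cols = {}
    for sample in design.index:
        p = truth.expected_read_proportions[sample].to_numpy()
        cols[sample] = rng.multinomial(total_reads, p)
    counts = pd.DataFrame(cols, index=truth.expected_read_proportions.index)
    meta = design[["tissue", "timepoint"]].copy()
    meta["total_reads"] = total_reads
    return CountMatrix(counts, meta)


def write_fastq(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "?" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_reference_fasta(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        for gene, seq in truth.transcripts.items():
            fh.write(f">{gene}\n{seq}\n")


def write_gene_map(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\n")
        for gene in truth.transcripts:
            fh.write(f"{gene}\t{gene}\n")


def write_design(truth: GroundTruth, path) -> None:
    truth.design.to_csv(path, sep="\t")


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "mito_length": len(truth.mito_genome),
        "mito_intervals": truth.mito_intervals,
        "injected_duplicate_read_ids": sorted(truth.injected_duplicate_read_ids),
        "samples": list(truth.design.index),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
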