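"""Gene x sample count matrices and upper-quartile normalization.

Counts are the number of reads assigned to each gene in each sample.  Samples
are only comparable within a tissue, so normalization is strictly per tissue:
each sample's counts are scaled so that its 75th-percentile gene count (over
genes expressed somewhere in that tissue) equals the tissue-mean upper
quartile, then rounded half-up back to integers so normalized values stay on
a counts-like scale.  No transcript-length correction is applied: without
reliable transcript lengths, expression is only compared across time points
within a single gene and tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizationFactors",
    "FoldChange",
    "count_reads",
    "upper_quartile_normalize",
    "fold_change",
]


@dataclass
class CountMatrix:
    """Non-negative integer read counts, genes (rows) x samples (columns),
    with per-sample metadata (tissue, time point, total assigned reads)."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index: sample id; columns: tissue, timepoint, total_reads

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns must match sample metadata index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("tissue", "timepoint", "total_reads"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def subset_tissue(self, tissue: str) -> "CountMatrix":
        keep = self.samples.index[self.samples["tissue"] == tissue]
        if len(keep) == 0:
            raise KeyError(f"no samples for tissue {tissue!r}")
        return CountMatrix(self.counts[keep].copy(), self.samples.loc[keep].copy())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene")


@dataclass
class NormalizationFactors:
    """Per-sample upper quartiles and scale factors for one tissue."""

    tissue: str
    upper_quartile: pd.Series  # per sample, 75th percentile of nonzero-in-tissue genes
    scale: pd.Series  # sample UQ / mean UQ across the tissue's samples
    reference_level: float  # mean upper quartile

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"upper_quartile": self.upper_quartile, "scale_factor": self.scale}
        )


@dataclass
class FoldChange:
    gene: str
    numerator: str
    denominator: str
    ratio: float
    lower_bound: bool = field(default=False)

    def __str__(self) -> str:
        prefix = "≥ " if self.lower_bound else ""
        return f"{self.gene}: {prefix}{self.ratio:.1f}-fold ({self.numerator} over {self.denominator})"


def count_reads(matches, design: pd.DataFrame, reference_genes=None, drop_all_zero: bool = True):
    """Tabulate gene-assignment matches into a :class:`CountMatrix`.

    Parameters
    ----------
    matches
        Iterable of objects (or (sample, gene) tuples) carrying ``sample``
        and ``gene`` attributes; ``gene`` of ``None`` means unmatched.
    design
        Sample metadata indexed by sample id with ``tissue`` and
        ``timepoint`` columns.
    reference_genes
        When given, all-zero rows for these genes are retained (subject to
        ``drop_all_zero``) so the matrix covers the full reference.
    drop_all_zero
        Drop genes with zero counts in every sample (default).

    Returns
    -------
    (CountMatrix, unmatched) where ``unmatched`` is a per-sample Series of
    reads that had no gene assignment (excluded from the matrix).
    """
    samples = list(design.index)
    tally: dict[tuple[str, str], int] = {}
    unmatched = {s: 0 for s in samples}
    for m in matches:
        sample, gene = (m if isinstance(m, tuple) else (m.sample, m.gene))
        if sample not in unmatched:
            raise KeyError(f"match references unknown sample {sample!r}")
        if gene is None:
            unmatched[sample] += 1
        else:
            tally[(gene, sample)] = tally.get((gene, sample), 0) + 1
    genes = sorted({g for g, _ in tally})
    if reference_genes is not None:
        genes = sorted(set(genes) | set(reference_genes))
    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int64)
    for (g, s), c in tally.items():
        counts.at[g, s] = c
    if drop_all_zero and len(counts):
        counts = counts.loc[counts.sum(axis=1) > 0]
    meta = design.copy()
    meta["total_reads"] = counts.sum(axis=0).reindex(samples).fillna(0).astype(int)
    return CountMatrix(counts, meta), pd.Series(unmatched, name="unmatched")


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(values + 0.5).astype(np.int64)


def upper_quartile_normalize(
    counts: CountMatrix, tissue: str, include_zero_genes: bool = False
) -> tuple[CountMatrix, NormalizationFactors]:
    """Upper-quartile normalize the samples of one tissue.

    Genes with zero counts across *all* of the tissue's samples are excluded
    from the quantile computation (configurable); the 75th percentile uses
    linear interpolation between order statistics.  Scale factor = sample UQ
    divided by the mean UQ across the tissue's samples; normalized counts are
    raw counts divided by the scale factor, rounded half-up to integers.
    """
    sub = counts.subset_tissue(tissue)
    if sub.counts.shape[1] < 2:
        raise ValueError(f"tissue {tissue!r} has fewer than 2 samples")
    mat = sub.counts.to_numpy(dtype=np.float64)
    if include_zero_genes:
        quant_rows = np.ones(mat.shape[0], dtype=bool)
    else:
        quant_rows = mat.sum(axis=1) > 0
    if not quant_rows.any():
        raise ValueError(f"tissue {tissue!r} has no expressed genes")
    uq = np.percentile(mat[quant_rows], 75, axis=0, method="linear")
    for sid, v in zip(sub.counts.columns, uq):
        if not v > 0:
            raise ValueError(f"sample {sid!r} has zero upper quartile; cannot normalize")
    zero_cols = [sid for sid, tot in zip(sub.counts.columns, mat.sum(axis=0)) if tot == 0]
    if zero_cols:
        raise ValueError(f"sample {zero_cols[0]!r} has all-zero counts; cannot normalize")
    reference = float(np.mean(uq))
    scale = uq / reference
    normalized = _round_half_up(mat / scale[np.newaxis, :])
    norm_df = pd.DataFrame(normalized, index=sub.counts.index, columns=sub.counts.columns)
    meta = sub.samples.copy()
    meta["total_reads"] = norm_df.sum(axis=0)
    factors = NormalizationFactors(
        tissue=tissue,
        upper_quartile=pd.Series(uq, index=sub.counts.columns, name="upper_quartile"),
        scale=pd.Series(scale, index=sub.counts.columns, name="scale_factor"),
        reference_level=reference,
    )
    return CountMatrix(norm_df, meta), factors


def fold_change(normalized: CountMatrix, gene: str, numerator: str, denominator: str) -> FoldChange:
    """Ratio of a gene's normalized counts between two samples/time points.

    A zero denominator yields a flagged ">= numerator-fold" lower bound
    rather than an error (a gene barely detectable outside its peak).
    ``numerator``/``denominator`` may be sample ids or time-point labels
    unique within the matrix.
    """

    def _col(label: str) -> str:
        if label in normalized.counts.columns:
            return label
        hits = normalized.samples.index[normalized.samples["timepoint"] == label]
        if len(hits) != 1:
            raise KeyError(f"label {label!r} is not a unique sample or time point")
        return hits[0]

    if gene not in normalized.counts.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    num = float(normalized.counts.at[gene, _col(numerator)])
    den = float(normalized.counts.at[gene, _col(denominator)])
    if den == 0:
        return FoldChange(gene, numerator, denominator, num, lower_bound=True)
    return FoldChange(gene, numerator, denominator, num / den)


def round_half_up(x: float) -> int:
    """Round half away from truncation toward +inf at .5 (Table-style rounding)."""
    return int(math.floor(x + 0.5))
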