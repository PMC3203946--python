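"""Demultiplexing, fixed trimming, and artificial-replicate removal.

Emulsion-PCR amplification occasionally puts more than one bead in a
droplet, generating many identical copies of one template and distorting a
gene's count.  The filter used here removes reads that are identical in
their first 36 (post-trim) bases when at least three such reads are present
at only one time point; one representative is retained so genuinely
expressed genes keep their evidence (removing the whole group is available
behind a flag, since either reading of "removing reads" is defensible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .simulate import Read

__all__ = [
    "DemuxTable",
    "TrimPolicy",
    "ReplicateFilterPolicy",
    "TrimReport",
    "RemovalReport",
    "demultiplex",
    "trim",
    "remove_artificial_replicates",
]


@dataclass
class DemuxTable:
    """MID barcode -> sample label."""

    entries: dict[str, str]
    mid_length: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("demux table is empty")
        lengths = {len(m) for m in self.entries}
        if len(lengths) != 1:
            raise ValueError("all MID sequences must have equal length")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("MID sequences must be unique")
        self.mid_length = lengths.pop()

    @classmethod
    def from_design(cls, design: pd.DataFrame) -> "DemuxTable":
        return cls({row["mid"]: sample for sample, row in design.iterrows()})


@dataclass
class TrimPolicy:
    trim_bases: int = 26
    min_post_trim_length: int = 1

    def __post_init__(self) -> None:
        if self.trim_bases < 0:
            raise ValueError("trim_bases must be >= 0")
        if self.min_post_trim_length < 0:
            raise ValueError("min_post_trim_length must be >= 0")


@dataclass
class ReplicateFilterPolicy:
    prefix_length: int = 36
    min_cluster: int = 3
    single_timepoint_only: bool = True
    keep_representative: bool = True

    def __post_init__(self) -> None:
        if self.prefix_length <= 0:
            raise ValueError("prefix_length must be > 0")
        if self.min_cluster < 2:
            raise ValueError("min_cluster must be >= 2")


@dataclass
class TrimReport:
    trimmed: int = 0
    discarded: int = 0


@dataclass
class RemovalReport:
    """Per-sample groups found and reads removed by the replicate filter."""

    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    removed_ids: set[str] = field(default_factory=set)

    def _bump(self, sample: str, key: str, by: int = 1) -> None:
        row = self.per_sample.setdefault(sample, {"groups_found": 0, "reads_removed": 0})
        row[key] += by

    @property
    def total_removed(self) -> int:
        return sum(v["reads_removed"] for v in self.per_sample.values())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.per_sample, orient="index").fillna(0).astype(int)
        df.index.name = "sample"
        return df


def demultiplex(reads: list[Read], table: DemuxTable) -> dict[str, list[Read]]:
    """Partition reads by exact MID match of the leading bases.

    Unmatched reads go to the ``"__unmatched__"`` bin; each read lands in
    exactly one bin.  Matching is exact — Roche MIDs are designed with high
    pairwise distance, so one substitution cannot cross barcodes.
    """
    if not reads:
        raise ValueError("no reads to demultiplex")
    bins: dict[str, list[Read]] = {sample: [] for sample in table.entries.values()}
    bins["__unmatched__"] = []
    k = table.mid_length
    for read in reads:
        sample = table.entries.get(read.sequence[:k])
        if sample is None:
            bins["__unmatched__"].append(read)
        else:
            read.sample = sample
            bins[sample].append(read)
    return bins


def trim(reads: list[Read], policy: TrimPolicy = TrimPolicy()) -> tuple[list[Read], TrimReport]:
    """Remove the first ``trim_bases`` bases (sequence and qualities) from
    every read; reads left shorter than ``min_post_trim_length`` are
    discarded and counted."""
    report = TrimReport()
    out: list[Read] = []
    t = policy.trim_bases
    for read in reads:
        if len(read.sequence) - t < policy.min_post_trim_length:
            report.discarded += 1
            continue
        out.append(
            Read(
                id=read.id,
                sequence=read.sequence[t:],
                quality=None if read.quality is None else read.quality[t:],
                sample=read.sample,
            )
        )
        report.trimmed += 1
    return out, report


def remove_artificial_replicates(
    reads_by_sample: dict[str, list[Read]],
    policy: ReplicateFilterPolicy = ReplicateFilterPolicy(),
    design: "pd.DataFrame | dict[str, str]" = None,
) -> tuple[dict[str, list[Read]], RemovalReport]:
    """Remove artificial sequence replicates across a set of samples.

    Reads are grouped by exact identity of their first ``prefix_length``
    bases (reads shorter than the prefix are grouped by their full
    sequence).  A group is collapsed when its members all fall in a single
    time point and its size is at least ``min_cluster``; one representative
    (the longest read, ties broken by lexicographically smallest
    identifier) is retained unless ``keep_representative`` is off.  Groups
    spanning two or more time points are left untouched.
    """
    if design is None:
        raise ValueError("a sample -> time point design is required")
    if isinstance(design, pd.DataFrame):
        tp_of = design["timepoint"].to_dict()
    else:
        tp_of = dict(design)
    for sample in reads_by_sample:
        if sample not in tp_of:
            raise KeyError(f"sample {sample!r} has no design entry")

    groups: dict[str, list[tuple[str, Read]]] = {}
    for sample, reads in reads_by_sample.items():
        for read in reads:
            key = read.sequence[: policy.prefix_length]
            groups.setdefault(key, []).append((sample, read))

    report = RemovalReport()
    drop: set[str] = set()
    for members in groups.values():
        if len(members) < policy.min_cluster:
            continue
        timepoints = {tp_of[sample] for sample, _ in members}
        if policy.single_timepoint_only and len(timepoints) > 1:
            continue
        sample0 = members[0][0]
        report._bump(sample0, "groups_found")
        ordered = sorted(members, key=lambda sr: (-len(sr[1].sequence), sr[1].id))
        victims = ordered[1:] if policy.keep_representative else ordered
        for sample, read in victims:
            drop.add(read.id)
            report.removed_ids.add(read.id)
            report._bump(sample, "reads_removed")
    filtered = {
        sample: [r for r in reads if r.id not in drop]
        for sample, reads in reads_by_sample.items()
    }
    return filtered, report
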