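"""Seeded nucleotide matching of contigs and reads to a reference
transcript set.

A k-mer index over both strands of the reference seeds hits; seeds are
chained per (transcript, strand, diagonal) band and the densest chain is
extended without gaps under an X-drop rule.  Scores use +1/match, -2/
mismatch and significance is a Karlin-Altschul-style e-value with the
classical ungapped nucleotide parameters, so a 1e-5 cutoff behaves the way
practitioners expect from ungapped BLASTn-like searches.  This matcher is a
deliberately simple stand-in for database BLAST searches: the
transcript-to-gene mapping is a required input, and identification rates
against real, versioned databases are out of its scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .assembly import revcomp
from .simulate import Read

__all__ = [
    "ReferenceIndex",
    "MatchResult",
    "build_index",
    "match",
    "summarize_identification",
]

#: Karlin-Altschul parameters for +1/-2 ungapped nucleotide scoring
KA_LAMBDA = 1.33
KA_K = 0.621

DEFAULT_K = 13
MISMATCH_PENALTY = 2
XDROP = 20


@dataclass
class MatchResult:
    query_id: str
    gene: str
    transcript: str
    strand: str
    alignment_length: int
    identity: float
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1:
            raise ValueError("identity must be in [0, 1]")


@dataclass
class ReferenceIndex:
    k: int
    transcripts: dict[str, str]
    gene_of: dict[str, str]
    seeds: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict, repr=False)
    total_length: int = 0

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")


def build_index(transcripts: dict[str, str], gene_of: dict[str, str], k: int = DEFAULT_K) -> ReferenceIndex:
    """Complete k-mer index over both strands of the reference."""
    if not transcripts:
        raise ValueError("empty reference")
    if len(set(transcripts)) != len(transcripts):
        raise ValueError("duplicate transcript identifiers")
    for tid in transcripts:
        if tid not in gene_of:
            raise ValueError(f"transcript {tid!r} missing from gene map")
    index = ReferenceIndex(k=k, transcripts=dict(transcripts), gene_of=dict(gene_of))
    seeds = index.seeds
    for tid, seq in transcripts.items():
        index.total_length += len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - k + 1):
                seeds.setdefault(s[i : i + k], []).append((tid, strand, i))
    return index


def _extend(query: str, target: str, q0: int, t0: int, length: int) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of an exact seed block.

    Returns (q_start, alignment_length, matches, mismatches).
    """
    score = length  # exact seed block
    matches, mismatches = length, 0
    # extend right
    best_score, best_right = score, 0
    q, t = q0 + length, t0 + length
    cur = score
    right_m = right_mm = 0
    m = mm = 0
    while q < len(query) and t < len(target):
        if query[q] == target[t]:
            cur += 1
            m += 1
        else:
            cur -= MISMATCH_PENALTY
            mm += 1
        if cur > best_score:
            best_score, best_right = cur, q - (q0 + length) + 1
            right_m, right_mm = m, mm
        if best_score - cur > XDROP:
            break
        q += 1
        t += 1
    score = best_score
    # extend left
    best_left = 0
    left_m = left_mm = 0
    cur = score
    best_score = score
    q, t = q0 - 1, t0 - 1
    m = mm = 0
    while q >= 0 and t >= 0:
        if query[q] == target[t]:
            cur += 1
            m += 1
        else:
            cur -= MISMATCH_PENALTY
            mm += 1
        if cur > best_score:
            best_score, best_left = cur, q0 - q
            left_m, left_mm = m, mm
        if best_score - cur > XDROP:
            break
        q -= 1
        t -= 1
    matches += right_m + left_m
    mismatches += right_mm + left_mm
    q_start = q0 - best_left
    aln_len = best_left + length + best_right
    return q_start, aln_len, matches, mismatches


def evalue(score: float, query_length: int, db_length: int) -> float:
    """Karlin-Altschul e-value for an ungapped nucleotide score."""
    return KA_K * query_length * db_length * math.exp(-KA_LAMBDA * score)


def match(query_id: str, query: str, index: ReferenceIndex, cutoff: float = 1e-5) -> MatchResult | None:
    """Best reference match for a query sequence, or None below ``cutoff``.

    Seeds are grouped per (transcript, strand, diagonal); the diagonal with
    the most seeds anchors an ungapped X-drop extension.  Ties are broken
    toward more identities, then lexicographically smaller gene id.
    """
    k = index.k
    if len(query) < k:
        raise ValueError(f"query {query_id!r} shorter than seed length {k}")
    bands: dict[tuple[str, str, int], list[int]] = {}
    for i in range(len(query) - k + 1):
        for tid, strand, pos in index.seeds.get(query[i : i + k], ()):
            bands.setdefault((tid, strand, pos - i), []).append(i)
    if not bands:
        return None
    results: list[MatchResult] = []
    # only the densest few bands need extension
    ranked = sorted(bands.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:8]
    for (tid, strand, diag), qpos_list in ranked:
        target = index.transcripts[tid] if strand == "+" else revcomp(index.transcripts[tid])
        q0 = min(qpos_list)
        t0 = q0 + diag
        q_start, aln_len, matches, mismatches = _extend(query, target, q0, t0, k)
        score = matches - MISMATCH_PENALTY * mismatches
        ev = evalue(score, len(query), index.total_length)
        if ev <= cutoff:
            results.append(
                MatchResult(
                    query_id=query_id,
                    gene=index.gene_of[tid],
                    transcript=tid,
                    strand=strand,
                    alignment_length=aln_len,
                    identity=matches / aln_len if aln_len else 0.0,
                    score=score,
                    evalue=ev,
                )
            )
    if not results:
        return None
    results.sort(key=lambda r: (-r.score, -r.identity * r.alignment_length, r.gene))
    return results[0]


@dataclass
class ReadAssignment:
    """A read's sample label and assigned gene (None = unidentified)."""

    sample: str
    gene: str | None


def assign_reads(
    reads: list[Read], index: ReferenceIndex, cutoff: float = 1e-5
) -> list[ReadAssignment]:
    """Match every read; reads shorter than the seed are unidentified."""
    out = []
    for read in reads:
        if read.sample is None:
            raise ValueError(f"read {read.id} has no sample label (demultiplex first)")
        if len(read.sequence) < index.k:
            out.append(ReadAssignment(read.sample, None))
            continue
        hit = match(read.id, read.sequence, index, cutoff)
        out.append(ReadAssignment(read.sample, hit.gene if hit else None))
    return out


def summarize_identification(
    assignments: list[ReadAssignment], mito_genes: set[str] | None = None
) -> pd.DataFrame:
    """Per-sample identification table: total reads, fraction identified,
    and fraction assigned to mitochondrial genes."""
    rows: dict[str, dict[str, float]] = {}
    for a in assignments:
        row = rows.setdefault(a.sample, {"total_reads": 0, "identified": 0, "mitochondrial": 0})
        row["total_reads"] += 1
        if a.gene is not None:
            row["identified"] += 1
            if mito_genes and a.gene in mito_genes:
                row["mitochondrial"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        return pd.DataFrame(columns=["total_reads", "identified_fraction", "mitochondrial_fraction"])
    df["identified_fraction"] = df["identified"] / df["total_reads"]
    df["mitochondrial_fraction"] = df["mitochondrial"] / df["total_reads"]
    df.index.name = "sample"
    return df[["total_reads", "identified_fraction", "mitochondrial_fraction"]].sort_index()
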