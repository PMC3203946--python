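"""Greedy overlap assembler and mitochondrial genome reconstruction.

A desk-scale overlap-layout-consensus assembler: it repeatedly merges the
contig pair with the longest suffix-prefix overlap (both orientations,
reverse complement included, contained sequences absorbed), with ties in
overlap length broken lexicographically by identifier so assemblies are
deterministic.  It is built for the scales this package simulates —
thousands of moderately long, low-error reads — not for production genome
assembly.

The mitochondrial genome is transcribed as one polycistronic primary
transcript that is processed into polyadenylated gene-level RNAs, so a
transcriptome's mito reads tile the whole genome and rare unprocessed
fragments span the junctions between neighbouring transcript units.
``reconstruct_mito`` orders transcript-derived contigs along a reference
gene order, merges overlapping ends, closes the circle when the terminal
contigs overlap, and reports gaps honestly when they do not.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .simulate import Read

__all__ = [
    "AssemblyParams",
    "Contig",
    "MitoAssembly",
    "assemble",
    "reconstruct_mito",
    "write_contigs_fasta",
    "write_mito_gff3",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AssemblyParams:
    min_overlap: int = 30
    max_mismatch_rate: float = 0.0
    min_identity_for_merge: float = 1.0

    def __post_init__(self) -> None:
        if self.min_overlap < 20:
            raise ValueError("min_overlap must be >= 20")
        if not 0 <= self.max_mismatch_rate <= 1:
            raise ValueError("max_mismatch_rate must be in [0, 1]")
        if not 0 <= self.min_identity_for_merge <= 1:
            raise ValueError("min_identity_for_merge must be in [0, 1]")


@dataclass
class Contig:
    id: str
    sequence: str
    depth: np.ndarray  # per-base read depth, same length as sequence
    members: list[tuple[str, int, str]]  # (read id, 0-based offset, strand)

    def __post_init__(self) -> None:
        if len(self.depth) != len(self.sequence):
            raise ValueError("depth length must equal consensus length")
        if not self.members:
            raise ValueError("contig must have at least one member read")

    @property
    def n_reads(self) -> int:
        return len(self.members)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


@dataclass
class MitoAssembly:
    sequence: str
    circular: bool
    gene_intervals: list[tuple[str, int, int, str]]  # 1-based inclusive; end < start wraps
    source_contigs: list[str]
    gaps: list[tuple[str, str]] = field(default_factory=list)  # (gene before, gene after)

    @property
    def length(self) -> int:
        return len(self.sequence)


class _Workspace:
    """Mutable assembly state: live contigs plus a k-mer membership index."""

    def __init__(self, seed_length: int):
        self.w = seed_length
        self.contigs: dict[str, dict] = {}
        self.index: dict[str, set[str]] = {}  # k-mer -> contigs containing it
        self.end_index: dict[str, set[str]] = {}  # k-mer -> contigs with it at an end
        self.counter = 0

    def add(self, seq: str, depth: np.ndarray, members: list) -> str:
        cid = f"ctg{self.counter:06d}"
        self.counter += 1
        rc = revcomp(seq)
        self.contigs[cid] = {"seq": seq, "rc": rc, "depth": depth, "members": members}
        for i in range(len(seq) - self.w + 1):
            self.index.setdefault(seq[i : i + self.w], set()).add(cid)
        if len(seq) >= self.w:
            for s in (seq, rc):
                self.end_index.setdefault(s[: self.w], set()).add(cid)
                self.end_index.setdefault(s[-self.w :], set()).add(cid)
        return cid

    def remove(self, cid: str) -> None:
        del self.contigs[cid]  # index entries are cleaned lazily

    def _lookup_in(self, table: dict[str, set[str]], kmer: str) -> set[str]:
        hits = table.get(kmer)
        if not hits:
            return set()
        live = {cid for cid in hits if cid in self.contigs}
        if len(live) != len(hits):
            table[kmer] = live
        return live

    def lookup(self, kmer: str) -> set[str]:
        return self._lookup_in(self.index, kmer)

    def lookup_end(self, kmer: str) -> set[str]:
        return self._lookup_in(self.end_index, kmer)


def _mismatches_ok(a: str, b: str, rate: float) -> bool:
    if rate <= 0:
        return a == b
    limit = int(rate * len(a))
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def _best_overlap(a: str, b: str, min_overlap: int, rate: float) -> int:
    """Longest s >= min_overlap with a[-s:] matching b[:s]; 0 if none."""
    if len(b) < min_overlap:
        return 0
    w = min(min_overlap, len(b))
    seed = b[:w]
    start = max(0, len(a) - len(b))
    p = a.find(seed, start)
    while p != -1:
        s = len(a) - p
        if s >= min_overlap and _mismatches_ok(a[p:], b[:s], rate):
            return s
        p = a.find(seed, p + 1)
    if rate > 0:
        # seed-exact search can miss mismatch-tolerant overlaps whose first
        # w bases differ; scan overlap sizes directly (desk-scale inputs)
        for s in range(min(len(a), len(b)), min_overlap - 1, -1):
            if _mismatches_ok(a[-s:], b[:s], rate):
                return s
    return 0


def _find_containment(a: str, b: str, rate: float) -> int:
    """Offset of b inside a (exact only), or -1."""
    if rate <= 0:
        return a.find(b)
    return a.find(b)  # mismatch-tolerant containment handled as overlap merges


def _pair_moves(ws: _Workspace, x: str, y: str, params: AssemblyParams):
    """All candidate merges between live contigs x and y.

    Yields (score, kind, a, b, orient, extra): kind "contain" absorbs b
    into a at offset extra; kind "join" appends b (oriented) after a with
    overlap extra.  ``orient`` is "+" or "-" for b's orientation.
    """
    cx, cy = ws.contigs[x], ws.contigs[y]
    rate = params.max_mismatch_rate
    moves = []
    for a_id, b_id in ((x, y), (y, x)):
        ca, cb = ws.contigs[a_id], ws.contigs[b_id]
        if len(cb["seq"]) <= len(ca["seq"]):
            for orient, bseq in (("+", cb["seq"]), ("-", cb["rc"])):
                pos = _find_containment(ca["seq"], bseq, rate)
                if pos != -1:
                    moves.append((len(bseq), "contain", a_id, b_id, orient, pos))
        for orient, bseq in (("+", cb["seq"]), ("-", cb["rc"])):
            s = _best_overlap(ca["seq"], bseq, params.min_overlap, rate)
            if s and s < min(len(ca["seq"]), len(bseq)):
                moves.append((s, "join", a_id, b_id, orient, s))
    return moves


def _candidates(ws: _Workspace, cid: str) -> set[str]:
    """Contigs that can interact with cid: those containing one of cid's
    end seeds, plus those whose own end seeds occur anywhere in cid (so a
    merged contig re-discovers reads now contained in its interior)."""
    c = ws.contigs[cid]
    w = ws.w
    seeds = set()
    for seq in (c["seq"], c["rc"]):
        if len(seq) >= w:
            seeds.add(seq[:w])
            seeds.add(seq[-w:])
    out: set[str] = set()
    for seed in seeds:
        out |= ws.lookup(seed)
    seq = c["seq"]
    for i in range(len(seq) - w + 1):
        hits = ws.end_index.get(seq[i : i + w])
        if hits:
            out |= ws.lookup_end(seq[i : i + w])
    out.discard(cid)
    return out


def _push_moves(ws: _Workspace, heap: list, cid: str, params: AssemblyParams) -> None:
    for other in sorted(_candidates(ws, cid)):
        for score, kind, a, b, orient, extra in _pair_moves(ws, cid, other, params):
            heapq.heappush(heap, (-score, a, b, kind, orient, extra))


def _apply_move(ws: _Workspace, move) -> str:
    _, a_id, b_id, kind, orient, extra = move
    ca, cb = ws.contigs[a_id], ws.contigs[b_id]
    b_seq = cb["seq"] if orient == "+" else cb["rc"]
    b_len = len(b_seq)
    b_depth = cb["depth"] if orient == "+" else cb["depth"][::-1]

    def flip_members(members, length):
        out = []
        for rid, off, strand in members:
            if orient == "+":
                out.append((rid, off, strand))
            else:
                # member occupies [off, off+mlen) of the forward contig; in the
                # reverse complement its offset is from the other end
                out.append((rid, off, "-" if strand == "+" else "+"))
        return out

    if kind == "contain":
        # absorb b into a in place: a's sequence is unchanged, so a's id,
        # index entries and pending heap moves all stay valid
        pos = extra
        ca["depth"][pos : pos + b_len] += b_depth
        ca["members"].extend(
            (rid, pos + (off if orient == "+" else b_len - off - _member_len(cb, rid)), st)
            for rid, off, st in flip_members(cb["members"], b_len)
        )
        ws.remove(b_id)
        return a_id
    else:
        s = extra
        shift = len(ca["seq"]) - s
        seq = ca["seq"] + b_seq[s:]
        depth = np.concatenate([ca["depth"], b_depth[s:]])
        depth[shift : shift + s] += b_depth[:s]
        members = ca["members"] + [
            (rid, shift + (off if orient == "+" else b_len - off - _member_len(cb, rid)), st)
            for rid, off, st in flip_members(cb["members"], b_len)
        ]
    ws.remove(a_id)
    ws.remove(b_id)
    return ws.add(seq, depth, members)


def _member_len(contig: dict, rid: str) -> int:
    # member read length is recoverable from recorded spans; store lazily
    return contig.setdefault("_mlen", {}).get(rid, 0)


def assemble(reads: list[Read], params: AssemblyParams = AssemblyParams()) -> list[Contig]:
    """Greedy overlap-layout-consensus assembly of trimmed, deduplicated
    reads into contigs.  Empty input yields an empty contig list."""
    if not reads:
        return []
    ws = _Workspace(seed_length=min(params.min_overlap, 24))
    mlens: dict[str, int] = {}
    for read in sorted(reads, key=lambda r: r.id):
        cid = ws.add(read.sequence, np.ones(len(read.sequence), dtype=np.int32),
                     [(read.id, 0, "+")])
        ws.contigs[cid]["_mlen"] = mlens
        mlens[read.id] = len(read.sequence)
    heap: list = []
    for cid in sorted(ws.contigs):
        _push_moves(ws, heap, cid, params)
    while heap:
        move = heapq.heappop(heap)
        _, a_id, b_id, kind, orient, extra = move
        if a_id not in ws.contigs or b_id not in ws.contigs:
            continue
        # contig sequences never change under their id, so a recorded move
        # with both endpoints alive is still applicable
        new_id = _apply_move(ws, move)
        if new_id != a_id:  # join created a new contig; containment mutates in place
            ws.contigs[new_id]["_mlen"] = mlens
            _push_moves(ws, heap, new_id, params)
    out = []
    for cid in sorted(ws.contigs):
        c = ws.contigs[cid]
        out.append(Contig(id=cid, sequence=c["seq"], depth=c["depth"], members=c["members"]))
    return out


def _shared_kmers(a: str, b: str, k: int = 21) -> int:
    if len(a) < k or len(b) < k:
        return 0
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    return sum(1 for i in range(len(b) - k + 1) if b[i : i + k] in sa)


def reconstruct_mito(
    contigs: list[Contig],
    gene_order: list[str],
    gene_transcripts: dict[str, str],
    params: AssemblyParams = AssemblyParams(),
) -> MitoAssembly:
    """Reconstruct a circular mitochondrial genome from transcript contigs.

    The largest contig matching each reference gene (by shared 21-mers,
    either strand) is selected; unique contigs are ordered by the reference
    gene order, oriented, and merged end-to-end where they overlap by at
    least ``min_overlap``.  If the terminal ends overlap the circle is
    closed and the overlap removed; otherwise a linear scaffold with
    annotated gaps is returned.  Gene intervals are located on the final
    sequence (1-based inclusive; an interval with end < start wraps the
    origin).
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    best: dict[str, tuple[int, str, str]] = {}  # gene -> (score, contig id, strand)
    by_id = {c.id: c for c in contigs}
    for gene in gene_order:
        ref = gene_transcripts[gene]
        scored = []
        for c in contigs:
            fwd = _shared_kmers(ref, c.sequence)
            rev = _shared_kmers(ref, revcomp(c.sequence))
            if max(fwd, rev) > 0:
                scored.append((max(fwd, rev), len(c.sequence), c.id, "+" if fwd >= rev else "-"))
        if scored:
            score, _, cid, strand = max(scored, key=lambda x: (x[0], x[1], x[2]))
            best[gene] = (score, cid, strand)
    if not best:
        raise ValueError("no contig matches any mitochondrial gene")

    chain: list[tuple[str, str]] = []  # (contig id, strand) in gene order, deduplicated
    seen = set()
    for gene in gene_order:
        if gene in best:
            _, cid, strand = best[gene]
            if cid not in seen:
                chain.append((cid, strand))
                seen.add(cid)

    pieces = [by_id[cid].sequence if strand == "+" else revcomp(by_id[cid].sequence)
              for cid, strand in chain]
    scaffold = pieces[0]
    gaps: list[tuple[str, str]] = []
    rate = params.max_mismatch_rate
    for i, piece in enumerate(pieces[1:], start=1):
        s = _best_overlap(scaffold, piece, params.min_overlap, rate)
        if s:
            scaffold = scaffold + piece[s:]
        else:
            pos = scaffold.find(piece)
            if pos != -1:
                continue  # already contained
            gaps.append((chain[i - 1][0], chain[i][0]))
            scaffold = scaffold + ("N" * 10) + piece
    circular = False
    if not gaps:
        s = _circular_overlap(scaffold, params.min_overlap, rate)
        if s:
            scaffold = scaffold[:-s]
            circular = True

    intervals = _locate_genes(scaffold, gene_order, gene_transcripts, circular)
    return MitoAssembly(
        sequence=scaffold,
        circular=circular,
        gene_intervals=intervals,
        source_contigs=[cid for cid, _ in chain],
        gaps=gaps,
    )


def _circular_overlap(seq: str, min_overlap: int, rate: float) -> int:
    """Longest s < len(seq) with the sequence's end matching its start."""
    limit = len(seq) - 1
    for s in range(min(limit, len(seq) // 2 + min_overlap), min_overlap - 1, -1):
        if _mismatches_ok(seq[-s:], seq[:s], rate):
            return s
    return 0


def _locate_genes(seq: str, gene_order, gene_transcripts, circular: bool):
    L = len(seq)
    search_space = seq + seq if circular else seq
    intervals = []
    for gene in gene_order:
        ref = gene_transcripts[gene]
        for strand, probe in (("+", ref), ("-", revcomp(ref))):
            pos = search_space.find(probe)
            if pos != -1 and (not circular or pos < L):
                start = pos + 1
                end = pos + len(probe)
                if circular and end > L:
                    end -= L
                intervals.append((gene, start, end, strand))
                break
    return intervals


def write_contigs_fasta(contigs: list[Contig], fasta_path, depth_path=None) -> None:
    with open(fasta_path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id} reads={c.n_reads}\n{c.sequence}\n")
    if depth_path is not None:
        with open(depth_path, "w") as fh:
            fh.write("contig\tposition\tdepth\n")
            for c in contigs:
                for i, d in enumerate(c.depth, start=1):
                    fh.write(f"{c.id}\t{i}\t{int(d)}\n")


def write_mito_gff3(assembly: MitoAssembly, path, seqid: str = "mito") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        topology = "circular" if assembly.circular else "linear"
        fh.write(f"# topology: {topology}\n")
        fh.write(f"##sequence-region {seqid} 1 {assembly.length}\n")
        for gene, start, end, strand in assembly.gene_intervals:
            if end >= start:
                fh.write(f"{seqid}\thibernaseq\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene}\n")
            else:  # wraps the origin: emit the two arcs
                fh.write(f"{seqid}\thibernaseq\tgene\t{start}\t{assembly.length}\t.\t{strand}\t.\tID={gene};part=1\n")
                fh.write(f"{seqid}\thibernaseq\tgene\t1\t{end}\t.\t{strand}\t.\tID={gene};part=2\n")
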