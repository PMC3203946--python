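"""Greedy overlap assembler and mitochondrial circle reconstruction."""

import numpy as np
import pytest

from hibernaseq.assembly import (
    AssemblyParams,
    assemble,
    reconstruct_mito,
    revcomp,
    _best_overlap,
    _circular_overlap,
)
from hibernaseq.simulate import Read, SimulationConfig, fragment_and_sample_reads, generate_reference


def R(rid, seq):
    return Read(id=rid, sequence=seq)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_params_validate():
    with pytest.raises(ValueError):
        AssemblyParams(min_overlap=10)
    with pytest.raises(ValueError):
        AssemblyParams(max_mismatch_rate=1.5)


def test_two_overlapping_reads_merge_exactly(rng):
    t = _random_seq(rng, 300)
    a, b = t[:180], t[130:]  # 50-base overlap
    contigs = assemble([R("a", a), R("b", b)], AssemblyParams(min_overlap=30))
    assert len(contigs) == 1
    assert contigs[0].sequence == t
    assert sorted(rid for rid, _, _ in contigs[0].members) == ["a", "b"]
    # depth 2 exactly on the overlap
    assert contigs[0].depth.max() == 2 and (contigs[0].depth == 2).sum() == 50


def test_reverse_complement_overlap_handled(rng):
    t = _random_seq(rng, 300)
    contigs = assemble([R("a", t[:180]), R("b", revcomp(t[130:]))], AssemblyParams(min_overlap=30))
    assert len(contigs) == 1
    assert contigs[0].sequence in (t, revcomp(t))


def test_no_overlap_yields_singletons(rng):
    a, b = _random_seq(rng, 100), _random_seq(rng, 100)
    contigs = assemble([R("a", a), R("b", b)], AssemblyParams(min_overlap=30))
    assert len(contigs) == 2
    assert all(c.is_singleton for c in contigs)


def test_contained_read_absorbed(rng):
    t = _random_seq(rng, 400)
    contigs = assemble([R("a", t), R("b", t[100:250])], AssemblyParams(min_overlap=30))
    assert len(contigs) == 1
    assert contigs[0].sequence == t
    assert (contigs[0].depth[100:250] == 2).all()


def test_empty_input_is_empty_output():
    assert assemble([], AssemblyParams()) == []


def test_tiled_reads_reconstruct_transcript_exactly(rng):
    """A deterministic 20x tiling of a 2000-base transcript assembles into
    one contig equal to the transcript."""
    t = _random_seq(rng, 2000)
    reads = []
    i = 0
    for start in range(0, 2000 - 400 + 1, 20):  # stride 20 => 380-base overlaps
        reads.append(R(f"r{i:04d}", t[start : start + 400]))
        i += 1
    reads.append(R(f"r{i:04d}", t[-400:]))
    contigs = assemble(reads, AssemblyParams(min_overlap=30))
    assert len(contigs) == 1
    assert contigs[0].sequence == t


def test_generator_reads_assemble_to_exact_substring():
    cfg = SimulationConfig(seed=9, n_tissues=1, n_timepoints=6, n_genes=1, reads_per_sample=25,
                           transcript_length_range=(2000, 2000), mito_fraction={"heart": 0.0})
    truth = generate_reference(cfg)
    reads = []
    for s in truth.design.index:
        for r in fragment_and_sample_reads(truth, cfg, s):
            r.sequence = r.sequence[26:]
            reads.append(r)
    contigs = assemble(reads, AssemblyParams(min_overlap=30))
    t = truth.transcripts["G0001"]
    best = max(contigs, key=lambda c: len(c.sequence))
    assert best.sequence in t  # 100% identity over the covered span
    assert len(best.sequence) >= 0.9 * len(t)


def test_read_conservation(small_run):
    truth, reads = small_run
    sub = [Read(r.id, r.sequence[26:]) for r in reads[:400]]
    contigs = assemble(sub, AssemblyParams(min_overlap=30))
    members = sorted(rid for c in contigs for rid, _, _ in c.members)
    assert members == sorted(r.id for r in sub)


def test_best_overlap_finds_longest():
    a = "A" * 10 + "ACGTACGTACGTACGTACGTACGTACGT"
    b = "ACGTACGTACGTACGTACGTACGTACGT" + "T" * 10
    s = _best_overlap(a, b, 20, 0.0)
    assert s == 28


def test_single_contig_circularization():
    rng = np.random.default_rng(0)
    genome = _random_seq(rng, 500)
    linear = genome + genome[:60]  # self-overlapping ends
    assert _circular_overlap(linear, 30, 0.0) == 60
    contig_reads = [R("a", linear)]
    from hibernaseq.assembly import Contig

    contig = Contig("c0", linear, np.ones(len(linear), dtype=int), [("a", 0, "+")])
    mito = reconstruct_mito([contig], ["GENE1"], {"GENE1": genome[10:200]},
                            AssemblyParams(min_overlap=30))
    assert mito.circular
    assert mito.length == 500


def test_reconstruct_reports_gap_when_junction_missing(rng):
    genome = _random_seq(rng, 2000)
    g1, g2 = genome[:900], genome[950:1800]  # 50-base hole between units
    from hibernaseq.assembly import Contig

    contigs = [
        Contig("c1", g1, np.ones(len(g1), dtype=int), [("r1", 0, "+")]),
        Contig("c2", g2, np.ones(len(g2), dtype=int), [("r2", 0, "+")]),
    ]
    mito = reconstruct_mito(contigs, ["A", "B"], {"A": g1[:500], "B": g2[:500]},
                            AssemblyParams(min_overlap=30))
    assert not mito.circular
    assert len(mito.gaps) == 1


def test_no_matching_contig_raises(rng):
    from hibernaseq.assembly import Contig

    c = Contig("c1", _random_seq(rng, 300), np.ones(300, dtype=int), [("r", 0, "+")])
    with pytest.raises(ValueError):
        reconstruct_mito([c], ["G"], {"G": _random_seq(rng, 300)})


def _rotate_truth_origin(truth, boundary_gene: str):
    """Rotate the circular genome so that `boundary_gene` starts at base 1;
    the circle, its transcript units and their cyclic order are unchanged."""
    import copy

    rotated = copy.deepcopy(truth)
    L = len(truth.mito_genome)
    idx = [i for i, (name, *_ ) in enumerate(truth.mito_intervals) if name == boundary_gene][0]
    r = truth.mito_intervals[idx][1] - 1
    rotated.mito_genome = truth.mito_genome[r:] + truth.mito_genome[:r]
    new_intervals = []
    for name, start, end, strand in truth.mito_intervals[idx:] + truth.mito_intervals[:idx]:
        new_intervals.append((name, (start - 1 - r) % L + 1, (end - 1 - r) % L + 1, strand))
    rotated.mito_intervals = new_intervals
    rotated.read_origins = {}
    return rotated


def _mito_circle_length(truth, cfg):
    reads = []
    for s in truth.design.index:
        for r in fragment_and_sample_reads(truth, cfg, s, n_reads=120):
            r.sequence = r.sequence[26:]
            reads.append(r)
    contigs = assemble(reads, AssemblyParams(min_overlap=30))
    mito = reconstruct_mito(contigs, truth.mito_genes,
                            {g: truth.transcripts[g] for g in truth.mito_genes},
                            AssemblyParams(min_overlap=30))
    assert mito.circular
    return mito.length


def test_mito_length_invariant_to_origin_rotation():
    """Rotating the planted genome's origin must not change the
    reconstructed circle length."""
    cfg = SimulationConfig(seed=13, n_tissues=1, n_timepoints=6, n_genes=1,
                           reads_per_sample=120, mito_fraction={"heart": 1.0},
                           junction_read_fraction=0.3, mito_length=4000)
    truth = generate_reference(cfg)
    rotated = _rotate_truth_origin(truth, "COX3")
    assert rotated.mito_genome != truth.mito_genome
    assert _mito_circle_length(truth, cfg) == 4000
    assert _mito_circle_length(rotated, cfg) == 4000
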