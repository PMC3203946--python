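"""Synthetic-data generator: determinism, planted effects, read structure."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from hibernaseq.simulate import (
    ConfigurationError,
    PlantedEffect,
    SimulationConfig,
    fragment_and_sample_reads,
    generate_reference,
    generate_run,
    inject_artificial_replicates,
    _trimmed_length_mean,
)


def test_invalid_configs_name_the_field():
    with pytest.raises(ConfigurationError, match="n_genes"):
        generate_reference(SimulationConfig(n_genes=0))
    with pytest.raises(ConfigurationError, match="read_length_mean"):
        SimulationConfig(read_length_mean=30.0).validate()
    with pytest.raises(ConfigurationError, match="duplicate_cluster_size"):
        SimulationConfig(duplicate_cluster_size=2).validate()
    with pytest.raises(ConfigurationError, match="fold"):
        SimulationConfig(planted_effects=(PlantedEffect("G0001", "heart", "Torpor", -1),)).validate()


def test_same_seed_reproduces_identical_truth_and_reads():
    cfg = SimulationConfig(seed=42, n_tissues=1, n_genes=10, reads_per_sample=50)
    t1, r1 = generate_run(cfg)
    t2, r2 = generate_run(cfg)
    assert t1.mito_genome == t2.mito_genome
    assert t1.transcripts == t2.transcripts
    assert [(r.id, r.sequence) for r in r1] == [(r.id, r.sequence) for r in r2]
    assert t1.expected_read_proportions.equals(t2.expected_read_proportions)


def test_planted_effect_multiplies_baseline_before_renormalization():
    base_cfg = SimulationConfig(seed=1, n_tissues=1, n_genes=20,
                                mito_fraction={"heart": 0.0})
    eff_cfg = SimulationConfig(seed=1, n_tissues=1, n_genes=20,
                               mito_fraction={"heart": 0.0},
                               planted_effects=(PlantedEffect("G0003", "heart", "Torpor", 8.0),))
    base = generate_reference(base_cfg).expected_read_proportions
    planted = generate_reference(eff_cfg).expected_read_proportions
    s = "heart_Torpor"
    # unnormalized weight of G0003 is 8x baseline: the ratio of proportions
    # equals 8 x (baseline normalizer / planted normalizer)
    ratio = planted.loc["G0003", s] / base.loc["G0003", s]
    other = planted.loc["G0010", s] / base.loc["G0010", s]
    assert ratio / other == pytest.approx(8.0, rel=1e-9)
    untouched = "heart_April"
    assert planted.loc["G0003", untouched] == pytest.approx(base.loc["G0003", untouched])


def test_proportions_sum_to_one_per_sample():
    truth = generate_reference(SimulationConfig(seed=2, n_genes=25))
    sums = truth.expected_read_proportions.sum(axis=0)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_mito_layout_tiles_circle_with_one_overlap():
    truth = generate_reference(SimulationConfig(seed=3, n_genes=5))
    intervals = truth.mito_intervals
    assert len(intervals) >= 10
    assert intervals[0][1] == 1 and intervals[-1][2] == len(truth.mito_genome)
    overlaps = 0
    for (n1, s1, e1, _), (n2, s2, e2, _) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            overlaps += 1
            assert (n1, n2) == ("ATP8", "ATP6")
        else:
            assert s2 == e1 + 1  # otherwise exactly adjacent
    assert overlaps == 1
    # transcript units are genome substrings
    for name, start, end, _ in intervals:
        assert truth.transcripts[name] == truth.mito_genome[start - 1 : end]


def test_reads_carry_mid_prefix_and_true_fragment(small_truth, small_config):
    reads = fragment_and_sample_reads(small_truth, small_config, "heart_April", n_reads=100)
    mid = small_truth.design.at["heart_April", "mid"]
    pad = small_truth.adaptor_pad_sequence
    for r in reads[:20]:
        assert r.sequence.startswith(mid + pad)
        gene, start, J = small_truth.read_origins[r.id]
        body = r.sequence[len(mid) + len(pad):]
        assert len(body) == J
        if gene != "MT-primary":
            assert body == small_truth.transcripts[gene][start - 1 : start - 1 + J]


def test_unknown_sample_rejected(small_truth, small_config):
    with pytest.raises(KeyError):
        fragment_and_sample_reads(small_truth, small_config, "liver_April")


def test_read_length_cap_at_transcript_length():
    cfg = SimulationConfig(seed=4, n_tissues=1, n_genes=5, reads_per_sample=200,
                           transcript_length_range=(60, 80), mito_fraction={"heart": 0.0},
                           read_length_mean=335.0)
    truth = generate_reference(cfg)
    reads = fragment_and_sample_reads(truth, cfg, "heart_April")
    for r in reads:
        gene, start, J = truth.read_origins[r.id]
        assert J <= len(truth.transcripts[gene])
        assert start == 1 or J < len(truth.transcripts[gene])


def test_mito_fraction_zero_produces_no_mito_reads():
    cfg = SimulationConfig(seed=5, n_tissues=1, n_genes=10, reads_per_sample=300,
                           mito_fraction={"heart": 0.0})
    truth = generate_reference(cfg)
    reads = fragment_and_sample_reads(truth, cfg, "heart_Torpor")
    mito = set(truth.mito_genes) | {"MT-primary"}
    assert all(truth.read_origins[r.id][0] not in mito for r in reads)


def test_trimmed_length_moments_converge(rng):
    cfg = SimulationConfig(seed=6, n_tissues=1, n_genes=3, reads_per_sample=100_000,
                           transcript_length_range=(5000, 5000), mito_fraction={"heart": 0.0})
    truth = generate_reference(cfg)
    reads = fragment_and_sample_reads(truth, cfg, "heart_April")
    lengths = np.array([truth.read_origins[r.id][2] for r in reads])
    a = (cfg.min_read_length - cfg.read_length_mean) / cfg.read_length_sd
    mean_expected = truncnorm.mean(a, np.inf, loc=cfg.read_length_mean, scale=cfg.read_length_sd)
    sd_expected = truncnorm.std(a, np.inf, loc=cfg.read_length_mean, scale=cfg.read_length_sd)
    assert lengths.mean() == pytest.approx(mean_expected, abs=4 * sd_expected / np.sqrt(len(lengths)))
    assert lengths.std() == pytest.approx(sd_expected, rel=0.02)
    assert _trimmed_length_mean(cfg) == pytest.approx(mean_expected)


def test_per_gene_counts_match_proportions_within_4_se():
    cfg = SimulationConfig(seed=7, n_tissues=1, n_genes=20, reads_per_sample=100_000,
                           mito_fraction={"heart": 0.0})
    truth = generate_reference(cfg)
    reads = fragment_and_sample_reads(truth, cfg, "heart_IBA")
    from collections import Counter

    observed = Counter(truth.read_origins[r.id][0] for r in reads)
    n = len(reads)
    for gene, p in truth.expected_read_proportions["heart_IBA"].items():
        if p == 0:
            assert observed[gene] == 0
            continue
        se = np.sqrt(n * p * (1 - p))
        assert abs(observed[gene] - n * p) < 4 * se + 1


def test_duplicate_injection_counts_and_identity(small_run, small_config):
    truth, reads = small_run
    inj = truth.injected_duplicate_read_ids
    k = small_config.duplicate_cluster_size
    assert len(inj) > 0 and len(inj) % (k - 1) == 0
    by_id = {r.id: r for r in reads}
    for rid in list(inj)[:10]:
        src = by_id[rid.split("_dup")[0]]
        assert by_id[rid].sequence == src.sequence
        assert rid > src.id  # copies sort after the original


def test_duplicate_rate_zero_is_identity(small_truth, small_config):
    from dataclasses import replace

    cfg = replace(small_config, duplicate_rate=0.0)
    reads = fragment_and_sample_reads(small_truth, cfg, "heart_March", n_reads=50)
    out = inject_artificial_replicates(reads, small_truth, cfg)
    assert [r.id for r in out] == [r.id for r in reads]
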