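"""Exact 2xk test: oracle equivalence, classical reductions, FDR, gene lists."""

import subprocess

import numpy as np
import pytest
from scipy.stats import fisher_exact as classical_fisher

from hibernaseq import destats
from hibernaseq.destats import (
    bh_fdr,
    de_gene_list,
    fisher_exact_2xk,
    fisher_exact_detail,
    _quick_bound,
)
from hibernaseq.quantify import CountMatrix
from hibernaseq.scenarios import _tissue_counts


def test_hand_enumerated_2x2_table():
    # margins 3/3, 3/3: probabilities 1/20, 9/20, 9/20, 1/20 over a=0..3
    assert fisher_exact_2xk([[3, 0], [0, 3]], "enumerate") == pytest.approx(0.1, rel=1e-9)
    assert fisher_exact_2xk([[3, 0], [0, 3]], "network") == pytest.approx(0.1, rel=1e-9)


def test_uniform_2x3_table_is_the_mode():
    for method in ("enumerate", "network"):
        assert fisher_exact_2xk([[1, 1, 1], [1, 1, 1]], method) == pytest.approx(1.0, rel=1e-9)


def test_empty_row_single_attainable_table():
    assert fisher_exact_2xk([[0, 0, 0], [5, 6, 7]]) == 1.0
    assert fisher_exact_2xk([[5, 6, 7], [0, 0, 0]]) == 1.0


def test_invalid_tables_rejected():
    with pytest.raises(ValueError):
        fisher_exact_2xk([[1, -1], [2, 2]])
    with pytest.raises(ValueError):
        fisher_exact_2xk([[1, 2, 3]])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_network_equals_enumeration_on_random_2x6(seed, rng=None):
    rng = np.random.default_rng(seed)
    for _ in range(25):
        c = rng.integers(30, 1500, size=6)
        n = int(rng.integers(1, 150))
        a = rng.multivariate_hypergeometric(c, n)
        t = np.vstack([a, c - a])
        pe = fisher_exact_2xk(t, "enumerate")
        pn = fisher_exact_2xk(t, "network")
        assert pn == pytest.approx(pe, rel=1e-6, abs=1e-300)


def test_2x2_reduces_to_classical_fisher(rng):
    for _ in range(300):
        t = rng.integers(0, 50, size=(2, 2))
        if t.sum() == 0:
            continue
        ours = fisher_exact_2xk(t, "enumerate")
        ref = classical_fisher(t)[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_column_permutation_invariance(rng):
    for _ in range(20):
        c = rng.integers(20, 400, size=6)
        n = int(rng.integers(1, 80))
        a = rng.multivariate_hypergeometric(c, n)
        t = np.vstack([a, c - a])
        perm = rng.permutation(6)
        p1 = fisher_exact_2xk(t, "enumerate")
        p2 = fisher_exact_2xk(t[:, perm], "enumerate")
        assert p2 == pytest.approx(p1, rel=1e-9)


def test_agrees_with_r_fexact_reference():
    """Independent cross-check against R's fisher.test (FEXACT network
    algorithm) on a handful of moderate 2x6 tables."""
    rng = np.random.default_rng(7)
    tables = []
    for _ in range(8):
        c = rng.integers(20, 120, size=6)
        n = int(rng.integers(5, 60))
        a = rng.multivariate_hypergeometric(c, n)
        tables.append(np.vstack([a, c - a]))
    lines = ["options(digits=15)"]
    for t in tables:
        flat = ",".join(str(x) for x in t.flatten())
        lines.append(
            f"cat(fisher.test(matrix(c({flat}),nrow=2,byrow=TRUE),workspace=2e8)$p.value,'\\n')"
        )
    try:
        proc = subprocess.run(["Rscript", "-e", ";".join(lines)],
                              capture_output=True, text=True, timeout=300)
    except (FileNotFoundError, subprocess.TimeoutExpired):
        pytest.skip("Rscript unavailable")
    r_values = [float(x) for x in proc.stdout.split()]
    assert len(r_values) == len(tables)
    for t, p_ref in zip(tables, r_values):
        assert fisher_exact_2xk(t, "enumerate") == pytest.approx(p_ref, rel=1e-5)


def test_null_pvalues_conservative_uniform(rng):
    """Under proportional columns the p-value distribution is stochastically
    >= uniform (one-sided KS)."""
    from scipy.stats import ks_1samp

    c = np.array([400, 380, 420, 390, 410, 400])
    pvals = []
    for _ in range(600):
        n = 60
        a = rng.multivariate_hypergeometric(c, n)
        pvals.append(fisher_exact_2xk(np.vstack([a, c - a]), "network"))
    # one-sided: empirical CDF should not exceed the uniform CDF markedly
    stat = max(np.mean(np.asarray(pvals) <= x) - x for x in np.linspace(0.01, 0.99, 50))
    assert stat < 0.06


def test_tiny_pvalues_do_not_underflow():
    c = np.array([100_000] * 6)
    a = np.array([50, 50, 4000, 50, 50, 50])
    p, tag, _ = fisher_exact_detail(np.vstack([a, c - a]))
    assert 0 < p <= 1e-13  # resolved far below the printed-p scale, not 0


def test_quick_bound_brackets_are_valid(rng):
    for _ in range(30):
        c = rng.integers(50, 500, size=6)
        n = int(rng.integers(1, 100))
        a = rng.multivariate_hypergeometric(c, n)
        t = np.vstack([a, c - a])
        lo, hi = _quick_bound(t)
        p = fisher_exact_2xk(t, "enumerate")
        assert lo - 1e-12 <= p <= hi + 1e-12


def test_montecarlo_estimates_match_exact(rng):
    for _ in range(5):
        c = rng.integers(100, 800, size=6)
        n = int(rng.integers(20, 120))
        a = rng.multivariate_hypergeometric(c, n)
        t = np.vstack([a, c - a])
        exact = fisher_exact_2xk(t, "enumerate")
        mc = fisher_exact_2xk(t, "montecarlo")
        se = max(np.sqrt(exact * (1 - exact) / 100_000), 1e-4)
        assert abs(mc - exact) < 6 * se


def test_bh_fdr_hand_computed_step_up():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_fdr([0.5]), [0.5])
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_fdr_matches_reference_step_up(rng):
    p = rng.random(200) ** 2
    m = len(p)
    order = np.argsort(p)
    q_ref = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):  # step-up from the largest p
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q_ref[i] = running
    np.testing.assert_allclose(bh_fdr(p), q_ref, rtol=1e-12)


def test_bh_fdr_rejects_bad_pvalues():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_fdr([-0.1])


def test_de_gene_list_cutoff_above_one_flags_everything():
    counts = _tissue_counts(seed=3, n_genes=40, totals=5000)
    results, summary = de_gene_list(counts, cutoff=1.1)
    assert summary.n_pass == summary.n_genes
    assert all(r.passes for r in results)


def test_de_gene_list_planted_gene_detected_and_annotated():
    from hibernaseq.scenarios import power_recovery

    out = power_recovery(seed=5, n_planted=3, n_genes=60, totals=8000)
    assert out["recovered"] == 3


def test_de_gene_list_requires_single_tissue(small_truth, small_config):
    import pandas as pd

    counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]}, index=["g1", "g2"])
    meta = pd.DataFrame({"tissue": ["heart", "wat"], "timepoint": ["April", "April"],
                         "total_reads": [3, 7]}, index=["a", "b"])
    with pytest.raises(ValueError):
        de_gene_list(CountMatrix(counts, meta))
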