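"""Count matrices, upper-quartile normalization, fold changes."""

import numpy as np
import pandas as pd
import pytest

from hibernaseq.quantify import (
    CountMatrix,
    count_reads,
    fold_change,
    upper_quartile_normalize,
)


def _design(samples, tissue="heart"):
    tps = ["April", "August", "October", "Torpor", "IBA", "March"]
    return pd.DataFrame({"tissue": tissue, "timepoint": tps[: len(samples)]}, index=samples)


def _matrix(data, tissue="heart"):
    counts = pd.DataFrame(data)
    meta = _design(list(counts.columns), tissue)
    meta["total_reads"] = counts.sum(axis=0)
    return CountMatrix(counts, meta)


class TestCountReads:
    def test_tabulation_and_unmatched_report(self):
        design = _design(["s1", "s2"])
        matches = [("s1", "g1")] * 10 + [("s1", None)] * 3 + [("s2", "g2")]
        matrix, unmatched = count_reads(matches, design)
        assert matrix.counts.at["g1", "s1"] == 10
        assert matrix.counts.at["g2", "s2"] == 1
        assert unmatched["s1"] == 3 and unmatched["s2"] == 0
        assert (matrix.samples["total_reads"] == matrix.counts.sum(axis=0)).all()

    def test_all_zero_rows_dropped_by_default_kept_on_request(self):
        design = _design(["s1", "s2"])
        matches = [("s1", "g1")]
        matrix, _ = count_reads(matches, design, reference_genes=["g1", "g2"])
        assert list(matrix.counts.index) == ["g1"]
        kept, _ = count_reads(matches, design, reference_genes=["g1", "g2"], drop_all_zero=False)
        assert list(kept.counts.index) == ["g1", "g2"]

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            count_reads([("sX", "g")], _design(["s1"]))

    def test_generator_totals_match(self, small_run, small_truth):
        truth, reads = small_run
        from hibernaseq.annotation import build_index, assign_reads
        from hibernaseq.simulate import Read

        idx = build_index(truth.transcripts, {g: g for g in truth.transcripts})
        labelled = [Read(r.id, r.sequence[26:], sample=r.id.split(":")[0]) for r in reads]
        assignments = assign_reads(labelled, idx)
        matrix, unmatched = count_reads([(a.sample, a.gene) for a in assignments],
                                        truth.design[["tissue", "timepoint"]])
        per_sample = matrix.counts.sum(axis=0) + unmatched
        for sample in truth.design.index:
            assert per_sample[sample] == sum(1 for r in labelled if r.sample == sample)


class TestUpperQuartile:
    def test_scale_equivariance_doubled_sample(self):
        a = np.array([1, 5, 10, 20, 40, 100, 7, 3])
        m = _matrix({"s1": a, "s2": 2 * a})
        normalized, factors = upper_quartile_normalize(m, "heart")
        assert (normalized.counts["s1"] == normalized.counts["s2"]).all()
        assert factors.scale["s2"] == pytest.approx(2 * factors.scale["s1"])

    def test_identical_samples_are_unchanged(self):
        a = np.array([2, 4, 8, 16, 32, 64])
        m = _matrix({"s1": a, "s2": a, "s3": a})
        normalized, factors = upper_quartile_normalize(m, "heart")
        np.testing.assert_array_equal(normalized.counts["s1"].to_numpy(), a)
        np.testing.assert_allclose(factors.scale, 1.0)

    def test_single_sample_tissue_rejected(self):
        m = _matrix({"s1": [1, 2, 3]})
        with pytest.raises(ValueError):
            upper_quartile_normalize(m, "heart")

    def test_all_zero_sample_named_in_error(self):
        m = _matrix({"s1": [1, 2, 3], "s2": [0, 0, 0]})
        with pytest.raises(ValueError, match="s2"):
            upper_quartile_normalize(m, "heart")

    def test_zero_genes_excluded_from_quantile(self):
        # an all-zero gene must not drag the upper quartile down
        base = {"s1": [10, 20, 30, 40, 0], "s2": [10, 20, 30, 40, 0]}
        with_zero = _matrix(base)
        normalized, factors = upper_quartile_normalize(with_zero, "heart")
        assert factors.upper_quartile["s1"] == np.percentile([10, 20, 30, 40], 75)

    def test_normalized_upper_quartiles_equalized(self, rng):
        data = {f"s{i}": rng.integers(0, 400, size=300) for i in range(6)}
        m = _matrix(data)
        normalized, factors = upper_quartile_normalize(m, "heart")
        uqs = []
        for s in normalized.counts:
            col = m.counts[s]
            nz = m.counts.sum(axis=1) > 0
            uqs.append(np.percentile(normalized.counts[s][nz], 75))
        assert max(uqs) - min(uqs) <= 1.5  # equal up to integer rounding

    def test_rank_order_preserved_within_sample(self, rng):
        data = {f"s{i}": rng.integers(0, 1000, size=50) for i in range(3)}
        m = _matrix(data)
        normalized, _ = upper_quartile_normalize(m, "heart")
        for s in normalized.counts:
            raw = m.counts[s].to_numpy()
            norm = normalized.counts[s].to_numpy()
            order = np.argsort(raw, kind="stable")
            assert (np.diff(norm[order]) >= -1).all()  # ties may swap by rounding only


class TestFoldChange:
    def test_published_malat1_wat_ratio(self):
        from hibernaseq.pipeline import published_normalized_counts

        s1 = published_normalized_counts()
        row = s1[(s1["gene"] == "MALAT1") & (s1["tissue"] == "wat")].iloc[0]
        assert round(row["October"] / row["March"], 1) == 4.5

    def test_ratio_and_reciprocal(self):
        m = _matrix({"s1": [10], "s2": [40]})
        fc = fold_change(m, m.counts.index[0], "s2", "s1")
        rc = fold_change(m, m.counts.index[0], "s1", "s2")
        assert fc.ratio == pytest.approx(4.0)
        assert fc.ratio * rc.ratio == pytest.approx(1.0)

    def test_equal_entries_give_one(self):
        m = _matrix({"s1": [7], "s2": [7]})
        assert fold_change(m, m.counts.index[0], "s1", "s2").ratio == 1.0

    def test_zero_denominator_reported_as_lower_bound(self):
        counts = pd.DataFrame({"s1": [50], "s2": [0]}, index=["ALBU"])
        meta = _design(["s1", "s2"])
        meta["total_reads"] = counts.sum(axis=0)
        m = CountMatrix(counts, meta)
        fc = fold_change(m, "ALBU", "s1", "s2")
        assert fc.lower_bound and fc.ratio == 50
        assert str(fc).startswith("ALBU: ≥ 50.0-fold")

    def test_timepoint_labels_resolve(self):
        m = _matrix({"s1": [10], "s2": [40]})
        fc = fold_change(m, m.counts.index[0], "August", "April")
        assert fc.ratio == pytest.approx(4.0)


def test_count_matrix_invariants():
    with pytest.raises(ValueError):
        _matrix({"s1": [-1, 2]})
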