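"""Welch tests, ANOVA/Tukey, BH, CV-IQR outliers, TDD statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tddseq.stats import (
    anova_tukey,
    bh_adjust,
    cv_outlier_filter,
    delta_dora_sensitivity,
    sensitivity_threshold,
    simple_differential_test,
    trimming_change_statistic,
    welch_t,
)

from conftest import lognormal_count_table


def oracle_cv_flags(counts: pd.DataFrame, samples: pd.DataFrame,
                    genotypes) -> set:
    """Sort-based quartile oracle for the CV-IQR outlier rule."""

    def quartile(sorted_vals, q):
        # linear interpolation between order statistics (type 7)
        h = (len(sorted_vals) - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, len(sorted_vals) - 1)
        return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

    cvs = {}
    for row in counts.index:
        for g in genotypes:
            ids = [i for i in samples.index if samples.at[i, "genotype"] == g]
            vals = counts.loc[row, ids].to_numpy(dtype=float)
            m = vals.mean()
            cvs[(row, g)] = vals.std(ddof=1) / m if m > 0 else np.nan
    finite = sorted(v for v in cvs.values() if np.isfinite(v))
    q1, q3 = quartile(finite, 0.25), quartile(finite, 0.75)
    lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
    return {row for (row, _g), v in cvs.items()
            if not np.isfinite(v) or v < lo or v > hi}


class TestWelch:
    def test_hand_computed_example(self):
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p == pytest.approx(0.2878, abs=1e-3)

    def test_identical_vectors_null(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, scale):
        a = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 5.0])
        b = welch_t([scale * x for x in (1.0, 2.0, 3.0)],
                    [scale * x for x in (2.0, 3.0, 5.0)])
        assert b.t == pytest.approx(a.t, rel=1e-9)
        assert b.p == pytest.approx(a.p, rel=1e-9)

    def test_zero_variance_conventions(self):
        equal = welch_t([2.0, 2.0], [2.0, 2.0])
        assert equal.p == 1.0 and equal.flag
        unequal = welch_t([2.0, 2.0], [3.0, 3.0])
        assert unequal.p == 0.0 and unequal.flag

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestAnovaTukey:
    def test_identical_groups_not_significant(self):
        omnibus, pairs = anova_tukey([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert omnibus > 0.99
        assert all(p > 0.99 for p in pairs.values())

    def test_planted_group_detected(self):
        jitter = [0.0, 0.01, -0.01]
        groups = [[0 + j for j in jitter], [0 + j for j in jitter],
                  [10 + j for j in jitter]]
        omnibus, pairs = anova_tukey(groups)
        assert omnibus < 1e-6
        assert pairs[(0, 2)] < 0.01 and pairs[(1, 2)] < 0.01
        assert pairs[(0, 1)] > 0.5

    def test_permutation_relabels_pairs(self):
        groups = [[1.0, 1.2, 0.9], [5.0, 5.5, 4.8], [1.1, 1.0, 1.3]]
        _, pairs_a = anova_tukey(groups)
        _, pairs_b = anova_tukey([groups[2], groups[1], groups[0]])
        assert pairs_a[(0, 1)] == pytest.approx(pairs_b[(1, 2)], rel=1e-9)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            anova_tukey([[1, 2], [1, 2], [3]])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_hand_step_up(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw(self, p):
        assert (bh_adjust(p) >= np.asarray(p) - 1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCvOutlierFilter:
    def test_identical_cvs_flag_nothing(self):
        ids = [f"{g}_c{i}" for g in ("WT", "dora") for i in (1, 2, 3)]
        samples = pd.DataFrame({"genotype": [i.split("_")[0] for i in ids],
                                "library_type": "total", "clone_id": ids},
                               index=pd.Index(ids))
        row = [10.0, 20.0, 30.0, 10.0, 20.0, 30.0]
        counts = pd.DataFrame([row, row, row], columns=ids,
                              index=["a", "b", "c"])
        kept, flags = cv_outlier_filter(counts, samples, ["WT", "dora"])
        assert len(flags) == 0 and len(kept) == 3

    def test_planted_spike_flagged_exactly(self):
        rng = np.random.default_rng(2)
        counts, samples = lognormal_count_table(rng, n_rows=50, sigma=0.1)
        spiked = counts.copy().astype(float)
        spiked.iloc[0, 0] *= 10  # one clone of one row blows up
        kept, flags = cv_outlier_filter(spiked, samples, ["WT", "dora"])
        assert set(flags["row"]) == {spiked.index[0]}
        assert set(flags["row"]) == oracle_cv_flags(spiked, samples,
                                                    ["WT", "dora"])

    def test_zero_mean_is_degenerate(self):
        rng = np.random.default_rng(3)
        counts, samples = lognormal_count_table(rng, n_rows=20, sigma=0.1)
        counts.iloc[1, :3] = 0.0  # WT clones all zero
        _, flags = cv_outlier_filter(counts, samples, ["WT", "dora"])
        degenerate = flags[flags["reason"].str.contains("degenerate")]
        assert counts.index[1] in set(degenerate["row"])

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            counts, samples = lognormal_count_table(
                rng, n_rows=int(rng.integers(8, 25)), sigma=0.3)
            _, flags = cv_outlier_filter(counts, samples, ["WT", "dora"])
            assert set(flags["row"]) == oracle_cv_flags(counts, samples,
                                                        ["WT", "dora"])

    def test_single_clone_errors(self):
        ids = ["WT_c1", "dora_c1", "dora_c2"]
        samples = pd.DataFrame({"genotype": ["WT", "dora", "dora"],
                                "library_type": "total", "clone_id": ids},
                               index=pd.Index(ids))
        counts = pd.DataFrame([[1.0, 2.0, 3.0]], columns=ids, index=["a"])
        with pytest.raises(ValueError):
            cv_outlier_filter(counts, samples, ["WT", "dora"])


class TestTddStatistics:
    def test_delta_sensitivity_examples(self):
        assert delta_dora_sensitivity(2.0, 2.0) == 0.0
        assert delta_dora_sensitivity(3.0, 1.0) == 2.0

    def test_trimming_identical_profiles_zero(self):
        f = [0.8, 0.05, 0.02, 0.01, 0.05, 0.04, 0.02, 0.01]
        assert trimming_change_statistic(f, f).delta == pytest.approx(0.0)

    def test_trimming_hand_sum(self):
        wt = [0.84, 0.03, 0.02, 0.01, 0.05, 0.02, 0.01, 0.02]
        dora = [0.76, 0.03, 0.02, 0.01, 0.10, 0.04, 0.02, 0.02]
        tc = trimming_change_statistic(wt, dora)
        assert tc.delta == pytest.approx(0.08)

    def test_trimming_rejects_bad_sums(self):
        good = [0.8, 0.05, 0.02, 0.01, 0.05, 0.04, 0.02, 0.01]
        bad = [0.9, 0.05, 0.02, 0.01, 0.05, 0.04, 0.02, 0.01]
        with pytest.raises(ValueError):
            trimming_change_statistic(good, bad)

    def test_sensitivity_threshold_rule(self):
        p = pd.Series([0.001, 0.01, 0.2, 0.04], index=list("abcd"))
        lfc = pd.Series([2.0, 1.5, -0.3, -0.2], index=list("abcd"))
        # smallest p among non-increases is 0.04 (d)
        assert sensitivity_threshold(p, lfc) == pytest.approx(0.04)
        assert sensitivity_threshold(p, pd.Series(1.0, index=list("abcd"))) \
            == np.inf


class TestDifferentialTest:
    def _fixture(self, seed=0, fold_rows=(), fold=4.0):
        rng = np.random.default_rng(seed)
        counts, samples = lognormal_count_table(rng, n_rows=60, sigma=0.1)
        counts = counts.astype(float)
        dora_ids = [i for i in counts.columns if i.startswith("dora")]
        for r in fold_rows:
            counts.loc[counts.index[r], dora_ids] *= fold
        sf = pd.Series(1.0, index=counts.columns)
        return counts, sf, samples

    def test_label_swap_flips_log2fc(self):
        counts, sf, samples = self._fixture(seed=5)
        a = simple_differential_test(counts, sf, samples, "dora", "WT")
        b = simple_differential_test(counts, sf, samples, "WT", "dora")
        np.testing.assert_allclose(a["log2FC"].to_numpy(),
                                   -b["log2FC"].to_numpy())

    def test_planted_fold_recovered(self):
        counts, sf, samples = self._fixture(seed=6, fold_rows=(0, 1, 2))
        res = simple_differential_test(counts, sf, samples, "dora", "WT")
        planted = res.iloc[:3]
        assert np.all(planted["log2FC"] > 1.5)
        assert np.all(planted["p_adj"] < 0.05)

    def test_requires_two_clones(self):
        counts, sf, samples = self._fixture()
        with pytest.raises(ValueError):
            simple_differential_test(counts.iloc[:, :4], sf, samples,
                                     "dora", "WT")

    def test_clone_order_invariance(self):
        counts, sf, samples = self._fixture(seed=9)
        shuffled = counts[list(counts.columns[::-1])]
        a = simple_differential_test(counts, sf, samples, "dora", "WT")
        b = simple_differential_test(shuffled, sf, samples, "dora", "WT")
        np.testing.assert_allclose(a["p"].to_numpy(), b["p"].to_numpy())
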