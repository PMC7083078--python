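"""Group inference: pooled t, Cohen's d, FDR, correlations, subgroup search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ctbskit import inference as inf
from ctbskit import (
    CohortConfig,
    auc_table,
    generate_cohort,
    preprocess_trials,
    timecourses,
)

finite_samples = st.lists(st.floats(-10, 10), min_size=3, max_size=15).filter(
    lambda xs: np.std(xs, ddof=1) > 1e-6)


def hand_pooled_t(a, b):
    """Textbook pooled-variance t implementation."""
    a, b = np.asarray(a), np.asarray(b)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, n1 + n2 - 2, p


def by_adjust_by_hand(p):
    """Benjamini–Yekutieli step-up with the harmonic-sum factor."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c = np.sum(1 / np.arange(1, m + 1))
    order = np.argsort(p)
    adj = p[order] * m * c / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestStudentsT:
    def test_identical_samples(self):
        t, df, p = inf.students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 4, pytest.approx(1.0))

    def test_hand_computed_example(self):
        t, df, _ = inf.students_t([0, 0, 0, 1, 1, 1], [1, 1, 1, 2, 2, 2])
        assert df == 10
        assert t == pytest.approx(-3.1623, abs=1e-4)

    @given(finite_samples, finite_samples)
    def test_matches_textbook_oracle(self, a, b):
        t, df, p = inf.students_t(a, b)
        t0, df0, p0 = hand_pooled_t(a, b)
        assert df == df0
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_constant_samples_equal_means(self):
        t, df, p = inf.students_t([2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_samples_unequal_means(self):
        with pytest.raises(inf.DegenerateVarianceError):
            inf.students_t([1.0, 1.0], [2.0, 2.0])


class TestCohensD:
    def test_identical_samples_zero(self):
        assert inf.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_unit_difference_unit_sd(self, rng):
        a = rng.normal(0, 1, 200)
        a = (a - a.mean()) / a.std(ddof=1)  # exact mean 0, sample SD 1
        b = a + 1.0  # identical shape, shifted: pooled SD 1, diff 1
        assert inf.cohens_d(a, b) == pytest.approx(1.0, abs=1e-12)

    @given(finite_samples, finite_samples)
    def test_t_d_identity(self, a, b):
        t, _, _ = inf.students_t(a, b)
        d = inf.cohens_d(a, b, signed=True)
        n1, n2 = len(a), len(b)
        assert d == pytest.approx(t * np.sqrt(1 / n1 + 1 / n2), abs=1e-9)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert inf.fdr_adjust([0.04])[0] == pytest.approx(0.04)

    def test_equal_ps_scaled_by_harmonic_sum(self):
        # m = 6: c(6) = 1 + 1/2 + ... + 1/6 = 2.45
        adjusted = inf.fdr_adjust([0.01] * 6)
        np.testing.assert_allclose(adjusted, 0.01 * 2.45)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_hand_by_and_dominates_raw_and_bh(self, p):
        by = inf.fdr_adjust(p, "by")
        np.testing.assert_allclose(by, by_adjust_by_hand(p), atol=1e-12)
        assert (by >= np.asarray(p) - 1e-12).all()
        assert (by >= inf.fdr_adjust(p, "bh") - 1e-12).all()

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=8)
        perm = rng.permutation(8)
        np.testing.assert_allclose(inf.fdr_adjust(p)[perm], inf.fdr_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(inf.InferenceError):
            inf.fdr_adjust([0.2, 1.4])


class TestPearsonCorr:
    def test_perfect_positive(self):
        assert inf.pearson_corr([1, 2, 3, 4], [1, 2, 3, 4]).r == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert inf.pearson_corr(x, -2 * x + 3).r == pytest.approx(-1.0)

    def test_hand_computed_small_table(self):
        # Σ(x-x̄)(y-ȳ) = 5.5, Σ(x-x̄)² = 5, Σ(y-ȳ)² = 8.75
        r_hand = 5.5 / np.sqrt(5 * 8.75)
        res = inf.pearson_corr([1, 2, 3, 4], [1, 3, 2, 5])
        assert res.r == pytest.approx(r_hand)
        # p from t = r sqrt((n-2)/(1-r^2)) with df = 2
        t = r_hand * np.sqrt(2 / (1 - r_hand**2))
        assert res.p_two_tailed == pytest.approx(2 * stats.t.sf(t, 2), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(inf.InferenceError):
            inf.pearson_corr([1, 1, 1], [1, 2, 3])


def _cohort_tables(config, seed):
    subjects, trials, _ = generate_cohort(config, seed=seed)
    _, blocks = preprocess_trials(trials)
    return auc_table(timecourses(blocks)), subjects


class TestCompareGroups:
    def test_positive_shift_recovered_in_every_interval(self):
        auc, subjects = _cohort_tables(CohortConfig(), seed=5)
        comps = inf.compare_groups(auc, subjects)
        assert len(comps) == 6
        for c in comps:
            assert c.mean_a > c.mean_b
            assert np.sign(c.cohens_d) == 1
            assert c.df == c.n_a + c.n_b - 2
            assert c.p_fdr >= c.p_raw - 1e-12

    def test_constant_equal_groups_give_t_zero(self):
        auc = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(8)] * 1,
            "interval_end_min": [10] * 8,
            "auc": [0.5] * 8,
            "delta_mep_max": [0.0] * 8,
        })
        subjects = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(8)],
            "group": ["ASD"] * 4 + ["TD"] * 4,
        })
        comps = inf.compare_groups(auc, subjects, intervals=[10])
        assert comps[0].t_stat == 0.0 and comps[0].p_raw == 1.0

    def test_small_interval_reported_not_computable(self):
        auc = pd.DataFrame({
            "subject_id": ["a1", "t1", "t2"],
            "interval_end_min": [10] * 3,
            "auc": [0.1, 0.2, 0.3],
            "delta_mep_max": [0.0] * 3,
        })
        subjects = pd.DataFrame({
            "subject_id": ["a1", "t1", "t2"],
            "group": ["ASD", "TD", "TD"],
        })
        comps = inf.compare_groups(auc, subjects, intervals=[10])
        assert np.isnan(comps[0].t_stat) and np.isnan(comps[0].p_fdr)


class TestSensitivityExcluding:
    def test_false_predicate_identical(self):
        auc, subjects = _cohort_tables(CohortConfig(), seed=9)
        full = inf.compare_groups(auc, subjects)
        rerun = inf.sensitivity_excluding(auc, subjects, lambda s: False)
        assert rerun == full

    def test_adhd_independent_effect_sign_preserved(self):
        auc, subjects = _cohort_tables(CohortConfig(), seed=9)
        rerun = inf.sensitivity_excluding(
            auc, subjects, lambda s: bool(s["adhd_comorbid"]))
        assert all(c.mean_a > c.mean_b for c in rerun)
        assert all(c.n_a < 11 for c in rerun)  # ADHD subjects really removed

    def test_exclude_all_of_one_group_raises(self):
        auc, subjects = _cohort_tables(CohortConfig(), seed=9)
        with pytest.raises(inf.InferenceError):
            inf.sensitivity_excluding(auc, subjects, lambda s: s["group"] == "ASD")


class TestBaselineMatchedSubgroups:
    def test_already_comparable_groups_returned_whole(self, rng):
        a = pd.Series(rng.normal(0.6, 0.1, 6), index=[f"a{i}" for i in range(6)])
        b = pd.Series(rng.normal(0.62, 0.1, 8), index=[f"b{i}" for i in range(8)])
        keep_a, keep_b = inf.select_baseline_matched_subgroups(a, b)
        assert set(keep_a) == set(a.index) and set(keep_b) == set(b.index)

    def test_trims_toward_overlapping_support(self):
        a = pd.Series([0.1] * 5, index=[f"a{i}" for i in range(5)])
        b = pd.Series([1.0] * 5 + [0.1], index=[f"b{i}" for i in range(6)])
        keep_a, keep_b = inf.select_baseline_matched_subgroups(a, b)
        assert len(keep_a) >= 2 and len(keep_b) >= 2
        _, _, p = inf.students_t(a[keep_a].to_numpy(), b[keep_b].to_numpy())
        assert p > 0.05

    def test_postcondition_at_printed_subgroup_scale(self, rng):
        # overlapping-baseline samples comparable to the n = 5 subgroups
        a = pd.Series(rng.normal(0.62, 0.17, 5), index=[f"a{i}" for i in range(5)])
        b = pd.Series(rng.normal(0.72, 0.17, 5), index=[f"b{i}" for i in range(5)])
        keep_a, keep_b = inf.select_baseline_matched_subgroups(a, b)
        _, _, p = inf.students_t(a[keep_a].to_numpy(), b[keep_b].to_numpy())
        assert p > 0.05

    def test_greedy_path_on_large_groups(self, rng):
        a = pd.Series(rng.normal(0.4, 0.25, 11), index=[f"a{i}" for i in range(11)])
        b = pd.Series(rng.normal(1.2, 0.4, 18), index=[f"b{i}" for i in range(18)])
        keep_a, keep_b = inf.select_baseline_matched_subgroups(a, b)
        assert len(keep_a) >= 2 and len(keep_b) >= 2
        _, _, p = inf.students_t(a[keep_a].to_numpy(), b[keep_b].to_numpy())
        assert p > 0.05
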