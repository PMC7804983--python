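"""Method-comparison statistics: formula oracles and behavioural properties."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flairvol.core import LesionMask, ValidationError
from flairvol.stats import (
    DegenerateTestError,
    age_association_glm,
    cohens_f,
    comparison_table,
    dice,
    effect_size_band,
    no_intercept_regression,
    paired_t_test,
    percent_volume_difference,
    top_lesion_load_subset,
    volume_difference_proportion,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon(diffs):
    """Independent oracle: two-sided p by full sign-pattern enumeration."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    expected = ranks.sum() / 2.0
    obs = abs(w_pos - expected)
    hits = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        wp = sum(r for s, r in zip(signs, ranks) if s)
        if abs(wp - expected) >= obs - 1e-12:
            hits += 1
    return hits / 2.0 ** len(d)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = m[1, 1, 2] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        b = np.zeros((3, 3, 3), dtype=bool)
        a[0, 0, 0] = True
        b[2, 2, 2] = True
        assert dice(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # TP=2, FP=1, FN=1 -> 2*2/(4+1+1) = 0.6667
        a = np.zeros((3, 3, 3), dtype=bool)
        b = np.zeros((3, 3, 3), dtype=bool)
        a[0, 0, 0] = a[0, 0, 1] = a[0, 0, 2] = True  # reference: 3 voxels
        b[0, 0, 0] = b[0, 0, 1] = b[1, 1, 1] = True  # 2 TP, 1 FP, 1 FN
        assert dice(a, b) == pytest.approx(2 * 2 / 6)

    def test_symmetry_and_empty_convention(self, rng):
        a = rng.random((4, 4, 4)) > 0.5
        b = rng.random((4, 4, 4)) > 0.5
        assert dice(a, b) == dice(b, a)
        empty = np.zeros((4, 4, 4), dtype=bool)
        assert dice(empty, empty) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dice(np.zeros((3, 3, 3), dtype=bool), np.zeros((4, 4, 4), dtype=bool))

    def test_accepts_lesion_masks(self, case_3t):
        assert dice(case_3t.truth_lesions, case_3t.truth_lesions) == 1.0


class TestVolumeDifferences:
    @pytest.mark.parametrize(
        "conv,flair,expected", [(2, 3, 0.5), (5, 5, 0.0), (2, 0, -1.0)]
    )
    def test_proportion(self, conv, flair, expected):
        assert volume_difference_proportion(conv, flair) == pytest.approx(expected)

    def test_proportion_needs_positive_reference(self):
        with pytest.raises(ValidationError):
            volume_difference_proportion(0.0, 1.0)

    @pytest.mark.parametrize(
        "conv,flair,expected", [(3, 1, 100.0), (4, 4, 0.0), (1, 3, -100.0)]
    )
    def test_percent(self, conv, flair, expected):
        assert percent_volume_difference(conv, flair) == pytest.approx(expected)

    def test_percent_antisymmetric(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 10, size=2)
            assert percent_volume_difference(a, b) == pytest.approx(
                -percent_volume_difference(b, a)
            )

    def test_percent_undefined_for_two_zeros(self):
        with pytest.raises(ValidationError):
            percent_volume_difference(0.0, 0.0)


class TestNoInterceptRegression:
    def test_exact_fit(self):
        r = no_intercept_regression([1, 2, 3], [2, 4, 6])
        assert r.beta == pytest.approx(2.0)
        assert r.se == 0.0
        assert r.r2 == pytest.approx(1.0)
        assert r.exact_fit

    def test_closed_form_example(self):
        assert no_intercept_regression([1, 2], [2, 3]).beta == pytest.approx(8 / 5)

    def test_matches_closed_form_on_random_fixtures(self, rng):
        for _ in range(100):
            n = rng.integers(3, 40)
            x = rng.normal(size=n) * 10
            y = 1.3 * x + rng.normal(size=n)
            r = no_intercept_regression(x, y)
            assert abs(r.beta - (x @ y) / (x @ x)) < 1e-12

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(1, 10, size=25)
        y = 1.05 * x + rng.normal(scale=0.3, size=25)
        ours = no_intercept_regression(x, y)
        theirs = sm.OLS(y, x).fit()
        assert ours.beta == pytest.approx(theirs.params[0], rel=1e-10)
        assert ours.r2 == pytest.approx(theirs.rsquared, rel=1e-8)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValidationError):
            no_intercept_regression([0, 0, 0], [1, 2, 3])

    def test_slope_recovery_simulation(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.uniform(400, 600, size=60)
            y = 1.02 * x + rng.normal(scale=0.01 * 500, size=60)
            if 0.99 <= no_intercept_regression(x, y).beta <= 1.05:
                hits += 1
        assert hits >= 90


class TestWilcoxon:
    def test_three_positive_differences(self):
        w, p = wilcoxon_signed_rank([1, 2, 3])
        assert w == 0.0  # rank sum against the positives
        assert p == pytest.approx(0.25)

    def test_antisymmetric_pairs_same_p(self, rng):
        d = rng.normal(size=9)
        assert wilcoxon_signed_rank(d)[1] == pytest.approx(wilcoxon_signed_rank(-d)[1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=-5, max_value=5).filter(lambda v: v != 0),
            min_size=1,
            max_size=8,
        )
    )
    def test_exact_p_matches_enumeration(self, diffs):
        # integer differences produce plenty of ties: the mid-rank path is hit
        _, p = wilcoxon_signed_rank(diffs)
        assert p == pytest.approx(brute_force_wilcoxon(diffs))

    def test_accepts_pairs(self):
        w1, p1 = wilcoxon_signed_rank([(3, 1), (5, 2), (4, 1)])
        w2, p2 = wilcoxon_signed_rank([2, 3, 3])
        assert (w1, p1) == (w2, p2)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_large_n_approximation_close_to_scipy(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = rng.normal(size=40) + 0.3
        _, p = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, method="approx", correction=True).pvalue
        assert p == pytest.approx(ref, abs=0.01)


class TestPairedT:
    def test_hand_closed_form(self):
        t, p = paired_t_test([1, 2, 3])
        assert t == pytest.approx(2 / (1 / math.sqrt(3)))

    def test_symmetric_differences_give_zero_t(self):
        t, p = paired_t_test([-2, -1, 1, 2])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_rel

        a, b = rng.normal(size=(2, 15))
        t, p = paired_t_test(np.c_[a, b])
        ref = ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_t_test([1.0, 1.0, 1.0])


class TestEffectSizes:
    def test_null_effect(self):
        assert cohens_f(0.4, 0.4) == 0.0

    def test_hand_arithmetic(self):
        assert cohens_f(0.5, 0.25) == pytest.approx(math.sqrt(0.5))

    def test_band_anchors(self):
        assert effect_size_band(0.05) == "negligible"
        assert effect_size_band(0.27) == "medium-to-large"
        assert effect_size_band(0.36) == "medium-to-large"
        assert effect_size_band(0.45) == "large"

    def test_full_r2_of_one_rejected(self):
        with pytest.raises(ValidationError):
            cohens_f(1.0, 0.5)


class TestAgeGlm:
    def make_cohort(self, rng, n=40, slope=-1.5):
        age = rng.uniform(18, 59, size=n)
        tiv = rng.normal(1500, 60, size=n)
        field = np.where(np.arange(n) % 2 == 0, "1.5T", "3T")
        gm = 500 + slope * (age - 38.5) + 0.1 * (tiv - 1500) + rng.normal(0, 5, size=n)
        return gm, age, tiv, field

    def test_recovers_negative_age_slope(self, rng):
        gm, age, tiv, field = self.make_cohort(rng)
        fit = age_association_glm(gm, age, tiv, field)
        assert fit["age_coefficient"] < 0
        assert fit["age_p"] < 0.05
        assert 0 <= fit["cohens_f_age"]
        assert fit["effect_band"] in {"negligible", "small-to-medium", "medium-to-large", "large"}

    def test_duplicated_subjects_leave_coefficients_unchanged(self, rng):
        gm, age, tiv, field = self.make_cohort(rng, n=20)
        fit1 = age_association_glm(gm, age, tiv, field)
        fit2 = age_association_glm(
            np.r_[gm, gm], np.r_[age, age], np.r_[tiv, tiv], np.r_[field, field]
        )
        assert fit1["age_coefficient"] == pytest.approx(fit2["age_coefficient"])

    def test_small_sample_rejected(self, rng):
        gm, age, tiv, field = self.make_cohort(rng, n=5)
        with pytest.raises(ValidationError):
            age_association_glm(gm, age, tiv, field)

    def test_collinear_design_rejected(self, rng):
        gm, age, tiv, field = self.make_cohort(rng)
        with pytest.raises(ValidationError, match="collinear"):
            age_association_glm(gm, age, np.full_like(age, 1500.0), field)


class TestComparisonTable:
    def planted_volumes(self, rng, n=10, bias=0.10):
        ref = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(1, 8, size=n))}
        other = {k: v * (1 + bias) for k, v in ref.items()}
        return {"multimodal": ref, "flair_only": other}

    def test_identical_methods(self, rng):
        vols = {m: {f"s{i}": float(i + 1) for i in range(5)} for m in ("a", "b")}
        masks = {
            m: {f"s{i}": LesionMask(np.ones((3, 3, 3), dtype=bool)) for i in range(5)}
            for m in ("a", "b")
        }
        tables = comparison_table(masks, vols)
        assert (tables["dice"].dice_mean == 1.0).all()
        assert (tables["wilcoxon"].flag == "degenerate").all()

    def test_planted_overestimation_recovered(self, rng):
        vols = self.planted_volumes(rng)
        tables = comparison_table(None, vols, reference_method="multimodal")
        med = tables["volume_diff"].median_vol_diff_proportion.iloc[0]
        assert med == pytest.approx(0.10, abs=0.01)

    def test_top_lesion_subset_is_max_subject(self, rng):
        vols = self.planted_volumes(rng)
        tables = comparison_table(None, vols, reference_method="multimodal")
        subset = tables["top_lesion_subset"]
        assert len(subset) == 1
        max_subject = max(vols["multimodal"], key=vols["multimodal"].get)
        assert subset.subject.iloc[0] == max_subject

    def test_top_lesion_load_subset_rule(self):
        loads = pd.Series({f"s{i}": float(i) for i in range(10)})
        subset = top_lesion_load_subset(loads, fraction=0.10)
        assert list(subset) == ["s9"]

    def test_single_method_rejected(self):
        with pytest.raises(ValidationError):
            comparison_table(None, {"only": {"s0": 1.0}})
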