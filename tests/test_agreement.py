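"""Concordance statistics, checked against brute-force moment oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from ivcfit import (
    DegenerateStatisticError,
    PairedSample,
    ValidationError,
    ccc_confidence_interval,
    classify_agreement,
    compare_dependent_ccc,
    fisher_z_ccc_test,
    lin_ccc,
    mean_diff_test,
    pearson_r,
)


def brute_force_ccc(x, y):
    """CCC straight from its moment definition with n-denominators."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sx2 = ((x - x.mean()) ** 2).mean()
    sy2 = ((y - y.mean()) ** 2).mean()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)


vectors = arrays(
    np.float64,
    st.integers(min_value=3, max_value=40),
    elements=st.floats(min_value=-50, max_value=50, allow_nan=False, width=64),
)


class TestCCC:
    def test_four_point_worked_example(self):
        # s^2 = 1.25 each, s_xy = 1.25, mean shift^2 = 1 -> 2.5 / 3.5
        assert lin_ccc(PairedSample(np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 5]))) == pytest.approx(
            0.7142857142857143, abs=1e-12
        )
        # exact reversal: equal means/variances, covariance -s^2 -> CCC = -1
        assert lin_ccc(PairedSample(np.array([1.0, 2, 3, 4]), np.array([4.0, 3, 2, 1]))) == pytest.approx(
            -1.0, abs=1e-12
        )
        # reversed and shifted mirrors the positive worked example
        assert lin_ccc(PairedSample(np.array([1.0, 2, 3, 4]), np.array([5.0, 4, 3, 2]))) == pytest.approx(
            -0.7142857142857143, abs=1e-12
        )

    def test_perfect_concordance(self):
        x = np.array([3.0, 5.0, 9.0])
        assert lin_ccc(PairedSample(x, x)) == pytest.approx(1.0, abs=1e-15)

    @given(x=vectors, y=vectors)
    def test_matches_brute_force_moments(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        sample = PairedSample(x, y)
        try:
            got = lin_ccc(sample)
        except DegenerateStatisticError:
            # only the 0/0 case may refuse: zero variances and zero
            # (possibly underflowed) squared mean shift
            assert x.var() == 0 and y.var() == 0
            assert (x.mean() - y.mean()) ** 2 == 0
            return
        assert got == pytest.approx(brute_force_ccc(x, y), abs=1e-12)
        assert -1.0 <= got <= 1.0

    @given(x=vectors)
    def test_ccc_never_exceeds_pearson_in_magnitude(self, x):
        rng = np.random.default_rng(0)
        y = x + rng.normal(2.0, 1.0, size=len(x))
        sample = PairedSample(x, y)
        try:
            c, r = lin_ccc(sample), pearson_r(sample)
        except DegenerateStatisticError:
            return
        assert abs(c) <= abs(r) + 1e-12

    def test_affine_invariance_of_shared_map(self):
        rng = np.random.default_rng(11)
        x = rng.normal(15, 3, 30)
        y = x + rng.normal(0, 1, 30)
        before = lin_ccc(PairedSample(x, y))
        after = lin_ccc(PairedSample(2.5 * x + 4, 2.5 * y + 4))
        assert after == pytest.approx(before, abs=1e-12)

    def test_constant_equal_vectors_undefined(self):
        with pytest.raises(DegenerateStatisticError):
            lin_ccc(PairedSample(np.full(5, 3.0), np.full(5, 3.0)))


class TestPearson:
    def test_exact_affine_relations(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(PairedSample(x, x + 1)) == pytest.approx(1.0)
        assert pearson_r(PairedSample(x, -x)) == pytest.approx(-1.0)

    def test_zero_variance_names_the_vector(self):
        x = np.array([1.0, 2, 3])
        with pytest.raises(DegenerateStatisticError, match="y"):
            pearson_r(PairedSample(x, np.full(3, 2.0)))


class TestClassification:
    @pytest.mark.parametrize(
        "ccc, expected",
        [
            (0.996, "excellent"),
            (0.152, "poor"),
            (0.431, "fair to good"),
            (0.40, "poor"),  # boundary belongs to the lower class
            (0.75, "fair to good"),
            (-1.0, "poor"),
            (1.0, "excellent"),
        ],
    )
    def test_taxonomy(self, ccc, expected):
        assert classify_agreement(ccc) == expected

    def test_sweep_yields_exactly_three_classes(self):
        classes = {classify_agreement(c) for c in np.linspace(-1.0, 1.0, 2001)}
        assert classes == {"poor", "fair to good", "excellent"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_agreement(1.5)


class TestConfidenceInterval:
    def test_interval_brackets_the_point_estimate(self, rng):
        x = rng.normal(15, 3, 40)
        y = x + rng.normal(0.5, 1.0, 40)
        res = ccc_confidence_interval(PairedSample(x, y))
        assert -1 < res.ci_low < res.ccc < res.ci_high < 1
        assert res.agreement_class == classify_agreement(res.ccc)
        assert abs(res.ccc) <= abs(res.pearson)

    def test_interval_narrows_with_sample_size(self, rng):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        widths = []
        for n in (20, 2000):
            xy = rng.multivariate_normal([10, 10], cov, size=n)
            res = ccc_confidence_interval(PairedSample(xy[:, 0], xy[:, 1]))
            widths.append(res.ci_high - res.ci_low)
        assert widths[1] < widths[0] / 3
        assert res.ccc == pytest.approx(0.9, abs=0.05)

    def test_identical_vectors_degenerate(self):
        x = np.array([1.0, 2, 3, 4])
        with pytest.raises(DegenerateStatisticError, match="CCC = 1"):
            ccc_confidence_interval(PairedSample(x, x))


class TestDependentComparison:
    def test_self_comparison_is_null(self, rng):
        common = rng.normal(12, 2, 24)
        cand = common + rng.normal(0, 1, 24)
        res = compare_dependent_ccc(common, cand, cand, n_boot=500, seed=1)
        assert res.delta == 0
        assert res.ci_low <= 0 <= res.ci_high
        assert res.p_value > 0.5

    def test_near_perfect_beats_noisy(self, rng):
        common = rng.normal(12, 2, 30)
        close = common + rng.normal(0, 0.1, 30)
        noisy = common + rng.normal(0, 2.5, 30)
        res = compare_dependent_ccc(common, close, noisy, n_boot=500, seed=2)
        assert res.delta > 0
        assert res.ci_low > 0
        assert res.p_value < 0.05
        assert res.fisher_z > 0 and res.fisher_z_p < 0.05

    def test_exactly_perfect_candidate_degrades_gracefully(self, rng):
        # CCC(a, a) = 1 has no Fisher-z transform; the bootstrap still works
        common = rng.normal(12, 2, 30)
        noisy = common + rng.normal(0, 2.5, 30)
        res = compare_dependent_ccc(common, common, noisy, n_boot=500, seed=3)
        assert res.delta > 0 and res.ci_low > 0 and res.p_value < 0.05
        assert np.isnan(res.fisher_z) and np.isnan(res.fisher_z_p)

    def test_deterministic_for_fixed_seed(self, rng):
        common = rng.normal(12, 2, 24)
        a = common + rng.normal(0, 0.5, 24)
        b = common + rng.normal(0, 1.5, 24)
        r1 = compare_dependent_ccc(common, a, b, n_boot=300, seed=42)
        r2 = compare_dependent_ccc(common, a, b, n_boot=300, seed=42)
        assert r1 == r2

    def test_seed_required_and_small_samples_rejected(self):
        v = np.arange(6.0)
        with pytest.raises(ValidationError, match="seed"):
            compare_dependent_ccc(v, v, v, n_boot=300)
        with pytest.raises(ValidationError, match="n >= 5"):
            compare_dependent_ccc(v[:4], v[:4], v[:4], n_boot=300, seed=1)


class TestMeanDiff:
    def test_constant_shift_paired(self):
        x = np.array([1.0, 2, 3, 4])
        res = mean_diff_test(x + 1, x, paired=True)
        assert res.mean_x - res.mean_y == pytest.approx(1.0)
        assert res.t_statistic == np.inf and res.p_value == 0.0
        # zero variance of differences is the degenerate path
        with pytest.raises(DegenerateStatisticError):
            mean_diff_test(x, x, paired=True)

    def test_two_sample_seeded_regression(self):
        rng = np.random.default_rng(123)
        g1 = rng.normal(12, 2, 30)
        g2 = rng.normal(12, 2, 30)
        res = mean_diff_test(g1, g2, paired=False)
        assert res.t_statistic == pytest.approx(1.0299162978039185, rel=1e-10)
        assert res.p_value == pytest.approx(0.307325164900572, rel=1e-10)
        assert res.df == 58

    def test_mismatched_paired_lengths_rejected(self):
        with pytest.raises(ValidationError):
            mean_diff_test(np.arange(4.0), np.arange(5.0), paired=True)
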