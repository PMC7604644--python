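"""Core transforms, intervals, coverage model and the weighted t-test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bafcnv.core import (
    CNV_TYPES,
    DELETION,
    DUPLICATION,
    CoverageModel,
    WeightedSample,
    binomial_ci,
    cf_from_vaf,
    cf_interval,
    expected_vaf,
    fit_coverage_model,
    fold_vaf,
    weighted_t_test,
    weighted_welch,
)


class TestVafTransforms:
    @pytest.mark.parametrize(
        "vaf,folded", [(0.67, 0.33), (0.5, 0.5), (0.0, 0.0), (1.0, 0.0), (0.33, 0.33)]
    )
    def test_fold_examples(self, vaf, folded):
        assert fold_vaf(vaf) == pytest.approx(folded)

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None)
    def test_fold_idempotent_and_bounded(self, v):
        f = fold_vaf(v)
        assert 0.0 <= f <= 0.5
        assert fold_vaf(f) == f

    def test_fold_domain_error(self):
        with pytest.raises(ValueError):
            fold_vaf(1.5)

    @pytest.mark.parametrize(
        "cnv_type,cf,expect",
        [
            (DELETION, 1.0, 0.0),          # full-clonal deletion removes the allele
            (DUPLICATION, 1.0, 1.0 / 3.0),  # 1 of 3 copies
            (DELETION, 0.5, 1.0 / 3.0),     # half-clonal deletion mimics clonal dup
            (DELETION, 0.0, 0.5),
            (DUPLICATION, 0.0, 0.5),
        ],
    )
    def test_expected_vaf_anchor_points(self, cnv_type, cf, expect):
        assert expected_vaf(cnv_type, cf) == pytest.approx(expect)

    @pytest.mark.parametrize("cnv_type", CNV_TYPES)
    def test_expected_vaf_strictly_decreasing(self, cnv_type):
        grid = np.linspace(0, 1, 101)
        vals = expected_vaf(cnv_type, grid)
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("cnv_type", CNV_TYPES)
    def test_cf_vaf_round_trip(self, cnv_type):
        grid = np.arange(0.0, 1.0001, 0.01)
        back = cf_from_vaf(cnv_type, expected_vaf(cnv_type, grid))
        assert np.allclose(back, grid, atol=1e-12)

    @pytest.mark.parametrize(
        "cnv_type,vaf,expect",
        [(DELETION, 0.5, 0.0), (DUPLICATION, 1.0 / 3.0, 1.0), (DELETION, 0.0, 1.0)],
    )
    def test_cf_from_vaf_examples(self, cnv_type, vaf, expect):
        assert cf_from_vaf(cnv_type, vaf) == pytest.approx(expect, abs=1e-12)

    def test_cf_from_vaf_duplication_divergence_clamped(self):
        # folded VAF 0 cannot arise from a copy number within [1, 3]
        assert cf_from_vaf(DUPLICATION, 0.0) == 1.0
        # folded VAF below 1/3 implies CF > 1 under the dup model -> clamped
        assert cf_from_vaf(DUPLICATION, 0.2) == 1.0

    def test_expected_vaf_domain_error(self):
        with pytest.raises(ValueError):
            expected_vaf(DELETION, 1.2)
        with pytest.raises(ValueError):
            expected_vaf("inversion", 0.5)


def _clopper_pearson_oracle(k, n, level):
    """Brute-force exact bounds by root-finding on the binomial CDF."""
    from scipy.optimize import brentq

    a = (1 - level) / 2
    lo = 0.0 if k == 0 else brentq(lambda p: stats.binom.sf(k - 1, n, p) - a, 1e-12, 1 - 1e-12)
    hi = 1.0 if k == n else brentq(lambda p: stats.binom.cdf(k, n, p) - a, 1e-12, 1 - 1e-12)
    return lo, hi


class TestBinomialCi:
    @pytest.mark.parametrize("k,n", [(33, 100), (0, 10), (10, 10), (1, 7), (250, 500)])
    def test_matches_exact_oracle(self, k, n):
        lo, hi = binomial_ci(k, n, 0.99)
        olo, ohi = _clopper_pearson_oracle(k, n, 0.99)
        assert lo == pytest.approx(olo, abs=1e-9)
        assert hi == pytest.approx(ohi, abs=1e-9)

    def test_contains_point_estimate(self, rng):
        n = rng.integers(1, 400, size=200)
        k = rng.binomial(n, rng.uniform(0, 1, size=200))
        lo, hi = binomial_ci(k, n, 0.99)
        assert np.all(lo <= k / n + 1e-12) and np.all(k / n <= hi + 1e-12)

    def test_boundaries(self):
        lo, hi = binomial_ci(0, 10, 0.99)
        assert lo == 0.0
        lo, hi = binomial_ci(10, 10, 0.99)
        assert hi == 1.0

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(0, 0, 0.99)


class TestCfInterval:
    def test_clonal_deletion(self):
        est = cf_interval(0, 200, DELETION)
        assert est.cf == pytest.approx(1.0)
        assert est.ci_high == pytest.approx(1.0)

    def test_heterozygous_contains_zero(self):
        est = cf_interval(100, 200, DELETION)
        assert est.ci_low == 0.0
        assert est.cf == pytest.approx(0.0, abs=1e-9)

    def test_duplication_endpoint_transform_oracle(self):
        est = cf_interval(66, 200, DUPLICATION)
        lo, hi = binomial_ci(66, 200, 0.99)
        # endpoints map through the decreasing transform and swap
        assert est.ci_high == pytest.approx(cf_from_vaf(DUPLICATION, lo))
        assert est.ci_low == pytest.approx(cf_from_vaf(DUPLICATION, hi))
        assert est.cf > 0.9

    @pytest.mark.parametrize("cnv_type", CNV_TYPES)
    def test_invariants_on_grid(self, cnv_type):
        for depth in (10, 50, 200):
            for alt in range(depth + 1):
                est = cf_interval(alt, depth, cnv_type)
                assert 0.0 <= est.ci_low <= est.cf <= est.ci_high <= 1.0

    @pytest.mark.parametrize("cnv_type", CNV_TYPES)
    def test_one_sided_intervals_reverse_order(self, cnv_type):
        # below 0.5 the transform is monotone decreasing in folded VAF
        for alt in range(0, 80):  # VAF CI stays below 0.5
            lo, hi = binomial_ci(alt, 200, 0.99)
            if hi >= 0.5:
                continue
            est = cf_interval(alt, 200, cnv_type)
            assert est.ci_low == pytest.approx(cf_from_vaf(cnv_type, hi))
            assert est.ci_high == pytest.approx(cf_from_vaf(cnv_type, lo))


class TestCoverageModel:
    def test_degenerate_fit(self):
        m = fit_coverage_model([100] * 50)
        assert np.exp(m.meanlog) == pytest.approx(100)
        assert m.sdlog == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery(self, rng):
        d = rng.lognormal(4.6, 0.5, size=10_000)
        m = fit_coverage_model(d)
        assert m.meanlog == pytest.approx(4.6, abs=0.05)
        assert m.sdlog == pytest.approx(0.5, abs=0.05)

    def test_zeros_excluded(self):
        m = fit_coverage_model([0] * 10 + [100] * 40)
        assert np.exp(m.meanlog) == pytest.approx(100)

    def test_too_few_depths(self):
        with pytest.raises(ValueError, match="30"):
            fit_coverage_model([100] * 29)

    def test_sampling_floor_and_integrality(self, rng):
        m = CoverageModel(meanlog=0.0, sdlog=1.0, min_depth=3)
        d = m.sample(rng, 1000)
        assert d.dtype.kind == "i"
        assert d.min() >= 3


class TestWeightedTTest:
    def test_symmetric_null(self):
        a = WeightedSample([0.1, 0.2, 0.3], [10, 20, 30])
        t, p = weighted_t_test(a, a, "greater")
        assert t == 0.0
        assert p == 0.5

    def test_equal_weights_match_welch(self, rng):
        for _ in range(200):
            na, nb = rng.integers(2, 15, size=2)
            a = rng.normal(0, 1, size=na)
            b = rng.normal(0.3, 1.5, size=nb)
            t, p = weighted_welch(a, np.ones(na), b, np.ones(nb), "greater")
            ref = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_fixed_example_matches_welch(self):
        a = np.array([0.8, 0.7, 0.9])
        b = np.array([0.0, 0.1, 0.05])
        _, p = weighted_welch(a, np.ones(3), b, np.ones(3), "greater")
        ref = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_weight_scale_invariance(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=6)
        wa, wb = rng.uniform(1, 50, 8), rng.uniform(1, 50, 6)
        r1 = weighted_welch(a, wa, b, wb, "greater")
        r2 = weighted_welch(a, 2 * wa, b, 2 * wb, "greater")
        assert r1 == pytest.approx(r2)

    def test_zero_variance_equal_means(self):
        t, p = weighted_welch([1, 1, 1], [5, 5, 5], [1, 1, 1], [2, 2, 2], "greater")
        assert (t, p) == (0.0, 0.5)

    def test_zero_variance_separated(self):
        _, p = weighted_welch([2, 2], [1, 1], [1, 1], [1, 1], "greater")
        assert p == 0.0
        _, p = weighted_welch([2, 2], [1, 1], [1, 1], [1, 1], "less")
        assert p == 1.0

    def test_inapplicable_when_neff_below_two(self):
        # a single dominant weight collapses the effective sample size
        with pytest.warns(UserWarning):
            _, p = weighted_t_test(
                WeightedSample([0.0, 1.0], [1e9, 1e-9]),
                WeightedSample([0.5, 0.6], [1, 1]),
            )
        assert np.isnan(p)

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            weighted_t_test(WeightedSample([1.0], [1.0]), WeightedSample([1, 2], [1, 1]))
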