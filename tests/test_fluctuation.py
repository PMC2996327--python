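"""Unit and property tests for Luria–Delbrück rate estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ofmkit.fluctuation import (
    EstimatorUndefinedError,
    FluctuationAssay,
    bootstrap_ci,
    estimate_lc_median,
    estimate_mss_mle,
    estimate_p0,
    lc_median_root,
    ld_log_likelihood,
    ld_pmf,
    rate_from_m,
    simulate_assay,
)


def make_assay(counts, size=10_000):
    return FluctuationAssay("test", tuple(counts), size)


class TestLdPmf:
    def test_no_events_when_m_zero(self):
        p = ld_pmf(0.0, 5)
        assert p[0] == 1.0
        assert np.all(p[1:] == 0.0)

    def test_one_step_of_recursion(self):
        # p0 = e^-1, p1 = (m/1) * p0/2
        p = ld_pmf(1.0, 1)
        assert p[0] == pytest.approx(np.exp(-1), abs=1e-12)
        assert p[1] == pytest.approx(np.exp(-1) / 2, abs=1e-12)

    @pytest.mark.parametrize("m", [0.0, 0.5, 1.0, 2.0, 5.0, 10.0])
    def test_zero_class_is_exactly_exp_minus_m(self, m):
        assert ld_pmf(m, 3)[0] == pytest.approx(np.exp(-m), abs=0)

    @pytest.mark.parametrize("m", [0.5, 2.0, 10.0])
    def test_mass_bounded_and_monotone_in_truncation(self, m):
        totals = [ld_pmf(m, r_max).sum() for r_max in (5, 20, 80, 320)]
        assert all(t <= 1.0 + 1e-12 for t in totals)
        assert all(a <= b + 1e-12 for a, b in zip(totals, totals[1:]))
        assert np.all(ld_pmf(m, 320) >= 0)

    def test_negative_m_rejected(self):
        with pytest.raises(ValueError):
            ld_pmf(-0.1, 5)

    def test_matches_simulated_count_distribution(self):
        # m = 2 via rate 2e-4 in cultures of 1e4 cells; total-variation
        # distance between the analytic pmf (tail mass lumped) and the
        # empirical histogram of 1e5 simulated cultures.
        r_max = 50
        p = ld_pmf(2.0, r_max)
        assay = simulate_assay(2e-4, 10_000, 100_000, seed=42)
        counts = assay.counts
        emp = np.bincount(np.minimum(counts, r_max + 1), minlength=r_max + 2) / len(counts)
        analytic = np.append(p, max(1.0 - p.sum(), 0.0))
        tv = 0.5 * np.abs(emp - analytic).sum()
        assert tv < 0.01


class TestP0:
    def test_all_zero_gives_zero(self):
        assert estimate_p0(make_assay([0] * 10)).m_hat == 0.0

    def test_half_zero_gives_ln_two(self):
        est = estimate_p0(make_assay([0] * 5 + [3, 1, 7, 2, 9]))
        assert est.m_hat == pytest.approx(np.log(2), rel=1e-12)
        assert est.method == "p0"

    def test_undefined_without_zero_class(self):
        with pytest.raises(EstimatorUndefinedError):
            estimate_p0(make_assay([1, 2, 3]))


class TestLeaCoulson:
    @pytest.mark.parametrize("median,expected", [(5, 2.37), (100, 22.9)])
    def test_known_roots(self, median, expected):
        m = lc_median_root(median)
        assert m == pytest.approx(expected, rel=0.01)
        # verify by substitution into the median equation
        assert median / m - np.log(m) == pytest.approx(1.24, abs=1e-9)

    def test_zero_median_rejected(self):
        with pytest.raises(EstimatorUndefinedError):
            estimate_lc_median(make_assay([0, 0, 0, 1]))

    def test_strictly_increasing_in_median(self):
        roots = [lc_median_root(r) for r in range(1, 60)]
        assert all(a < b for a, b in zip(roots, roots[1:]))

    def test_uses_lower_median(self):
        # even n: counts {2, 10} -> lower median 2
        est = estimate_lc_median(make_assay([2, 10]))
        assert est.m_hat == pytest.approx(lc_median_root(2))


class TestMssMle:
    def test_all_zero_boundary(self):
        with pytest.warns(UserWarning):
            est = estimate_mss_mle(make_assay([0] * 20))
        assert est.m_hat == 0.0

    def test_matches_grid_search(self):
        # 50 identical cultures with r=3: the MLE maximizes ln p_3(m); compare
        # against an exhaustive grid at step 1e-3.
        assay = make_assay([3] * 50)
        est = estimate_mss_mle(assay)
        grid = np.arange(0.5, 6.0, 1e-3)
        lls = [ld_log_likelihood(m, assay.counts) for m in grid]
        assert est.m_hat == pytest.approx(grid[int(np.argmax(lls))], abs=2e-3)

    def test_likelihood_peaks_inside_bracket(self):
        assay = simulate_assay(5e-4, 10_000, 100, seed=5)
        est = estimate_mss_mle(assay)
        ll_opt = ld_log_likelihood(est.m_hat, assay.counts)
        pilot = lc_median_root(assay.lower_median())
        assert ll_opt >= ld_log_likelihood(pilot / 10, assay.counts)
        assert ll_opt >= ld_log_likelihood(pilot * 10, assay.counts)

    def test_parameter_recovery(self):
        hits = sum(
            abs(estimate_mss_mle(simulate_assay(5e-4, 10_000, 200, seed=300 + s)).m_hat - 5) / 5
            <= 0.15
            for s in range(20)
        )
        assert hits >= 16


class TestEstimatorConsistency:
    @pytest.mark.parametrize("m", [1.0, 2.0, 5.0])
    def test_three_estimators_agree_on_simulated_assays(self, m):
        vals = {"p0": [], "lc": [], "mss": []}
        for s in range(20):
            a = simulate_assay(m / 10_000, 10_000, 500, seed=100 + s)
            try:
                vals["p0"].append(estimate_p0(a).m_hat)
            except EstimatorUndefinedError:
                pass
            vals["lc"].append(estimate_lc_median(a).m_hat)
            vals["mss"].append(estimate_mss_mle(a).m_hat)
        medians = {k: np.median(v) for k, v in vals.items()}
        pairs = [("p0", "lc"), ("p0", "mss"), ("lc", "mss")]
        for a, b in pairs:
            assert abs(medians[a] - medians[b]) / max(medians[a], medians[b]) < 0.25


class TestRateConversion:
    def test_division(self):
        assert rate_from_m(2.0, 1000) == pytest.approx(2e-3)
        assert rate_from_m(0.0, 1000) == 0.0

    def test_wild_type_headline_scale(self):
        # m = 2.1 in a 1000-cell culture gives the wild-type gapped-derivative
        # loss rate of 2.1e-3 per division
        assert rate_from_m(2.1, 1000) == pytest.approx(2.1e-3)

    def test_sampled_cultures_scale_by_cells_scored(self):
        full = FluctuationAssay("x", (2, 3, 0, 1), 10_000)
        thin = FluctuationAssay("x", (2, 3, 0, 1), 10_000, cells_sampled=1_000)
        assert estimate_p0(thin).rate_per_division == pytest.approx(
            10 * estimate_p0(full).rate_per_division
        )


class TestBootstrap:
    def test_deterministic_given_seed(self):
        assay = simulate_assay(5e-4, 10_000, 60, seed=9)
        ci1 = bootstrap_ci(assay, "lc_median", 200, 0.95, seed=7)
        ci2 = bootstrap_ci(assay, "lc_median", 200, 0.95, seed=7)
        assert ci1 == ci2

    def test_degenerate_assay_zero_width(self):
        lo, hi = bootstrap_ci(make_assay([4] * 30), "lc_median", 200, 0.95, seed=1)
        assert lo == hi == pytest.approx(lc_median_root(4))

    def test_coverage_of_true_m(self):
        hits = 0
        for s in range(60):
            a = simulate_assay(5e-4, 10_000, 100, seed=1000 + s)
            lo, hi = bootstrap_ci(a, "lc_median", 400, 0.95, seed=s)
            hits += lo <= 5.0 <= hi
        assert hits >= 54  # ~90% of replicates


class TestSimulateAssay:
    def test_zero_rate_all_zero(self):
        assert all(c == 0 for c in simulate_assay(0.0, 1000, 50, seed=0).culture_counts)

    def test_zero_class_fraction_matches_poisson_events(self):
        # a culture has zero losses iff zero events: P = e^-m with m = 2
        a = simulate_assay(2e-4, 10_000, 100_000, seed=1)
        frac = np.mean(a.counts == 0)
        assert frac == pytest.approx(np.exp(-2), abs=0.01)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_assay(1.5, 1000, 10, seed=0)

    def test_deterministic_given_seed(self):
        a = simulate_assay(5e-4, 10_000, 50, seed=3)
        b = simulate_assay(5e-4, 10_000, 50, seed=3)
        assert a.culture_counts == b.culture_counts

    @pytest.mark.parametrize("m_true", [1.0, 5.0, 20.0])
    def test_round_trip_recovery(self, m_true):
        hits = 0
        for s in range(20):
            a = simulate_assay(m_true / 10_000, 10_000, 200, seed=500 + s)
            est = estimate_lc_median(a) if a.lower_median() > 0 else estimate_p0(a)
            rate = est.rate_per_division
            hits += abs(rate - m_true / 10_000) / (m_true / 10_000) <= 0.20
        assert hits >= 16


class TestAssayValidation:
    def test_counts_cannot_exceed_culture_size(self):
        with pytest.raises(ValueError):
            make_assay([10_001], size=10_000)

    def test_needs_at_least_one_culture(self):
        with pytest.raises(ValueError):
            make_assay([])

    @given(st.integers(min_value=-5, max_value=-1))
    def test_negative_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            make_assay([1, bad])
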