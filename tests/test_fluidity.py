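"""Extremal-index (dynamics fluidity) estimation."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from fluideeg.core import InvalidArgument, MultichannelSeries
from fluideeg.fluidity import (
    estimate_extremal_index,
    fluidity_timeseries,
    log_distance_series,
    suveges_theta,
)
from fluideeg.synthetic import gen_iid_gaussian, gen_var1


def suveges_numeric(gaps, p, use_t_gaps=False):
    """Independent oracle: maximize the Süveges log-likelihood numerically."""
    T = np.asarray(gaps, dtype=float)
    S = T if use_t_gaps else T - 1.0
    n = S.size
    nc = int((S > 0).sum())
    s_sum = p * S.sum()
    if s_sum == 0:
        return 0.0

    def nll(theta):
        return -(
            (n - nc) * np.log1p(-theta) + 2 * nc * np.log(theta) - theta * s_sum
        )

    res = minimize_scalar(
        nll, bounds=(1e-12, 1 - 1e-12), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


class TestLogDistance:
    def test_unit_distance_gives_zero_g(self, make_series):
        values = np.zeros((3, 200))
        values[0, 50] = 1.0  # unit step on one channel
        g = log_distance_series(make_series(values), ref_index=0)
        i = np.where(g.times == 50)[0][0]
        assert g.g[i] == pytest.approx(0.0)

    def test_three_four_five_triangle(self, make_series):
        values = np.array([[0.0, 3.0], [0.0, 4.0]])
        series = MultichannelSeries(values, rate=1.0)
        g = log_distance_series(series, ref_index=0)
        assert g.g[0] == pytest.approx(-np.log(5.0))

    def test_amplitude_doubling_shifts_g_by_log2(self, iid_eeg):
        g1 = log_distance_series(iid_eeg.series, ref_index=10)
        doubled = iid_eeg.series.copy_with(values=2.0 * iid_eeg.series.values)
        g2 = log_distance_series(doubled, ref_index=10)
        np.testing.assert_allclose(g2.g, g1.g - np.log(2.0), atol=1e-12)

    def test_self_point_excluded(self, iid_eeg):
        g = log_distance_series(iid_eeg.series, ref_index=42)
        assert 42 not in g.times
        assert np.all(np.isfinite(g.g))

    def test_duplicate_reference_points_excluded_with_warning(self, make_series):
        values = np.random.default_rng(0).standard_normal((4, 300))
        values[:, 200] = values[:, 5]  # exact duplicate of the reference
        with pytest.warns(UserWarning, match="duplicate"):
            g = log_distance_series(make_series(values), ref_index=5)
        assert 200 not in g.times
        assert g.n_zero_excluded == 1

    def test_ref_index_out_of_range(self, make_series):
        with pytest.raises(InvalidArgument):
            log_distance_series(make_series(np.zeros((2, 100))), ref_index=100)


class TestSuvegesEstimator:
    def test_closed_form_matches_numerical_mle_on_random_patterns(self):
        """The closed form solves the Süveges score equation: it must agree
        with direct numerical likelihood maximization on arbitrary
        exceedance patterns."""
        rng = np.random.default_rng(2024)
        p = 0.02
        for _ in range(50):
            n_gaps = rng.integers(5, 200)
            # mixture of adjacent (gap 1) and spread-out exceedances
            adjacent = rng.random(n_gaps) < rng.random()
            gaps = np.where(adjacent, 1, rng.integers(2, 500, size=n_gaps))
            if gaps.max() == 1 or gaps.min() > 1:
                gaps[0] = 1
                gaps[-1] = 50
            closed = suveges_theta(gaps, p=p)
            numeric = suveges_numeric(gaps, p=p)
            assert closed == pytest.approx(numeric, abs=1e-6)

    def test_regular_exceedances_match_oracle(self):
        # exceedances at {10, 20, 30, 40} -> gaps {10, 10, 10}
        gaps = np.array([10.0, 10.0, 10.0])
        closed = suveges_theta(gaps, p=0.02)
        assert closed == pytest.approx(suveges_numeric(gaps, p=0.02), abs=1e-6)
        assert 0 < closed <= 1

    def test_t_gap_variant_also_matches_oracle(self):
        gaps = np.array([1.0, 5.0, 1.0, 30.0, 2.0])
        closed = suveges_theta(gaps, p=0.05, use_t_gaps=True)
        numeric = suveges_numeric(gaps, p=0.05, use_t_gaps=True)
        assert closed == pytest.approx(numeric, abs=1e-6)

    def test_contiguous_run_gives_theta_zero(self):
        """A single block of adjacent exceedances is the fixed-point limit."""
        g = np.zeros(1000)
        g[400:420] = 10.0  # one contiguous run above the 98% threshold
        theta, n_exc = estimate_extremal_index(g, q=0.98)
        assert theta == 0.0
        assert n_exc == 20

    def test_fewer_than_two_exceedances_gives_nan(self):
        g = np.zeros(200)
        g[50] = 5.0
        theta, n_exc = estimate_extremal_index(g, q=0.99)
        assert np.isnan(theta)

    def test_short_series_gives_nan(self):
        theta, _ = estimate_extremal_index(np.random.default_rng(0).random(50))
        assert np.isnan(theta)

    def test_iid_series_theta_near_one(self):
        g = np.random.default_rng(5).standard_normal(100_000)
        theta, _ = estimate_extremal_index(g, q=0.98)
        assert theta == pytest.approx(1.0, abs=0.05)

    def test_invalid_quantile(self):
        with pytest.raises(InvalidArgument):
            estimate_extremal_index(np.random.default_rng(0).random(200), q=1.5)


class TestFluidityTimeseries:
    def test_iid_gaussian_mean_theta_near_poisson_limit(self):
        thetas = []
        for seed in range(3):
            eeg = gen_iid_gaussian(10, 4000, seed=seed)
            fl = fluidity_timeseries(eeg.series, ref_stride=200)
            thetas.append(fl.mean_theta)
        assert 0.9 <= np.mean(thetas) <= 1.0

    def test_persistent_series_less_fluid_than_iid(self, ar_eeg, iid_eeg):
        fl_ar = fluidity_timeseries(ar_eeg.series, ref_stride=100)
        fl_iid = fluidity_timeseries(iid_eeg.series, ref_stride=100)
        assert fl_ar.mean_theta < fl_iid.mean_theta

    def test_degenerate_stride_single_reference(self, iid_eeg):
        fl = fluidity_timeseries(iid_eeg.series, ref_stride=iid_eeg.series.n_samples)
        assert fl.theta.size == 1

    def test_amplitude_scaling_invariance(self, iid_eeg):
        fl1 = fluidity_timeseries(iid_eeg.series, ref_stride=250)
        scaled = iid_eeg.series.copy_with(values=7.3 * iid_eeg.series.values)
        fl2 = fluidity_timeseries(scaled, ref_stride=250)
        np.testing.assert_allclose(fl1.theta, fl2.theta, atol=1e-10)

    def test_channel_permutation_invariance(self, iid_eeg):
        fl1 = fluidity_timeseries(iid_eeg.series, ref_stride=250)
        perm = np.random.default_rng(1).permutation(iid_eeg.series.n_channels)
        permuted = MultichannelSeries(
            iid_eeg.series.values[perm], rate=iid_eeg.series.rate
        )
        fl2 = fluidity_timeseries(permuted, ref_stride=250)
        np.testing.assert_allclose(fl1.theta, fl2.theta, atol=1e-10)

    def test_monotone_in_persistence(self):
        means = []
        for rho in (0.0, 0.7, 0.97):
            vals = []
            for seed in range(3):
                eeg = gen_var1(4, 4000, persistence=rho, seed=100 + seed)
                vals.append(fluidity_timeseries(eeg.series, ref_stride=200).mean_theta)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_time_reversal_leaves_theta_distribution(self, ar_eeg):
        """Forward and time-reversed stationary series have the same
        fluidity distribution (KS test non-significant)."""
        from scipy.stats import ks_2samp

        fl_fwd = fluidity_timeseries(ar_eeg.series, ref_stride=50)
        reversed_series = ar_eeg.series.copy_with(
            values=ar_eeg.series.values[:, ::-1].copy()
        )
        fl_rev = fluidity_timeseries(reversed_series, ref_stride=50)
        _, p = ks_2samp(fl_fwd.valid_theta, fl_rev.valid_theta)
        assert p > 0.05

    def test_sigma_positive_where_theta_defined(self, iid_eeg):
        fl = fluidity_timeseries(iid_eeg.series, ref_stride=300)
        ok = np.isfinite(fl.theta)
        assert np.all(fl.sigma[ok] > 0)

    def test_phase_boundary_censoring_runs(self, make_series):
        from fluideeg.preprocess import concat_phases

        rng = np.random.default_rng(3)
        a = make_series(rng.standard_normal((4, 600)))
        b = make_series(rng.standard_normal((4, 600)))
        joined = concat_phases([a, b])
        fl = fluidity_timeseries(joined, ref_stride=150, censor_phase_boundaries=True)
        assert np.isfinite(fl.theta).any()
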