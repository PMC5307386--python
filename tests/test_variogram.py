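"""Semivariogram estimation, model evaluation, fitting and selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socmap import (FAMILIES, EmpiricalVariogram, VariogramError,
                    VariogramFit, empirical_semivariogram, fit_model,
                    generate_locations, model_gamma, select_model,
                    simulate_gaussian_field)

DOMAIN = (0.0, 0.0, 40_000.0, 70_000.0)


class TestEmpiricalSemivariogram:
    def test_two_point_estimate_forced_by_definition(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        ev = empirical_semivariogram(coords, [3.0, 7.0], n_lags=1,
                                     max_lag=150.0)
        assert ev.gamma == pytest.approx([8.0])
        assert ev.pair_counts == pytest.approx([1.0])

    def test_constant_field_is_flat_zero(self, default_coords):
        ev = empirical_semivariogram(default_coords,
                                     np.full(len(default_coords), 5.0))
        np.testing.assert_allclose(ev.gamma, 0.0)

    def test_matches_generating_model_below_range(self):
        truth = VariogramFit("spherical", 0.05, 0.15, 20_000.0)
        pts = generate_locations(500, DOMAIN, 0.0, seed=4)
        z = simulate_gaussian_field(pts, truth, seed=4)
        ev = empirical_semivariogram(pts, z)
        below = ev.lag_centers < truth.range_
        rel = np.abs(ev.gamma[below] - truth.gamma(ev.lag_centers[below])) \
            / truth.gamma(ev.lag_centers[below])
        assert rel.mean() < 0.20

    def test_shift_invariance_and_quadratic_scaling(self, default_coords,
                                                    rng):
        z = rng.normal(size=len(default_coords))
        a = empirical_semivariogram(default_coords, z)
        b = empirical_semivariogram(default_coords, z + 100.0)
        c = empirical_semivariogram(default_coords, 3.0 * z)
        np.testing.assert_allclose(a.gamma, b.gamma, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(9.0 * a.gamma, c.gamma, rtol=1e-9)

    def test_pair_count_budget(self, default_coords, rng):
        z = rng.normal(size=len(default_coords))
        ev = empirical_semivariogram(default_coords, z)
        n = len(default_coords)
        assert ev.pair_counts.sum() <= n * (n - 1) / 2


class TestModelGamma:
    def test_spherical_reaches_sill_at_range(self):
        assert model_gamma("spherical", 0.0427, 0.1314 - 0.0427, 30_900.0,
                           30_900.0) == pytest.approx(0.1314)

    def test_zero_lag_convention(self):
        for fam in FAMILIES:
            assert model_gamma(fam, 0.05, 0.1, 1000.0, 0.0) == 0.0
            assert model_gamma(fam, 0.05, 0.1, 1000.0, 1e-6) == pytest.approx(
                0.05, abs=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(st.sampled_from(FAMILIES), st.floats(0, 0.2), st.floats(0.01, 0.5),
           st.floats(100, 50_000))
    def test_monotone_in_lag(self, fam, nug, psill, rng_):
        h = np.linspace(1e-9, 2.5 * rng_, 200)
        g = model_gamma(fam, nug, psill, rng_, h)
        assert np.all(np.diff(g) >= -1e-12)

    def test_negative_parameters_rejected(self):
        with pytest.raises(VariogramError):
            model_gamma("spherical", -0.1, 0.1, 1000.0, 10.0)
        with pytest.raises(VariogramError):
            model_gamma("spherical", 0.1, 0.1, -1000.0, 10.0)


class TestFitModel:
    def _exact_ev(self, family, nugget, sill, range_):
        lags = np.linspace(1_000.0, 24_000.0, 12)
        gam = model_gamma(family, nugget, sill - nugget, range_, lags)
        return EmpiricalVariogram(lag_centers=lags, gamma=gam,
                                  pair_counts=np.full(12, 50.0),
                                  max_lag=24_000.0, n_lags=12)

    @pytest.mark.parametrize("family", ["spherical", "exponential",
                                        "gaussian"])
    def test_noiseless_recovery(self, family):
        ev = self._exact_ev(family, 0.05, 0.15, 18_000.0)
        fit = fit_model(ev, family)
        assert fit.nugget == pytest.approx(0.05, rel=1e-4, abs=1e-6)
        assert fit.sill == pytest.approx(0.15, rel=1e-4)
        assert fit.range_ == pytest.approx(18_000.0, rel=1e-3)
        assert fit.r2 > 0.9999

    @pytest.mark.parametrize("nugget,sill,ratio", [
        (0.0427, 0.1314, 32.49), (0.0918, 0.2166, 42.38),
        (0.0947, 0.3514, 26.95), (0.0549, 0.1418, 38.72),
    ])
    def test_nugget_to_sill_classification(self, nugget, sill, ratio):
        fit = VariogramFit("spherical", nugget, sill, 20_000.0)
        assert fit.nugget_to_sill == pytest.approx(ratio, abs=0.01)
        assert fit.dependence_class == "moderate"

    def test_long_range_fit_on_white_noise_recovers_variance(self,
                                                             default_coords):
        z = np.random.default_rng(7).normal(0, 1.0, len(default_coords))
        ev = empirical_semivariogram(default_coords, z)
        fit = fit_model(ev, "spherical")
        # within the observed lag window the fitted level must sit at the
        # sample variance (the range itself is unidentified on white noise)
        level = fit.gamma(ev.max_lag)
        assert level == pytest.approx(z.var(ddof=1), rel=0.25)

    def test_too_few_bins_rejected(self):
        ev = EmpiricalVariogram(lag_centers=np.array([1.0, 2.0, 3.0]),
                                gamma=np.ones(3), pair_counts=np.ones(3),
                                max_lag=3.0, n_lags=3)
        with pytest.raises(VariogramError):
            fit_model(ev, "spherical")


class TestSelectModel:
    def _fit(self, family, r2, rss):
        return VariogramFit(family, 0.05, 0.15, 10_000.0, r2=r2, rss=rss)

    def test_single_candidate(self):
        f = self._fit("gaussian", 0.5, 0.1)
        assert select_model([f]) is f

    def test_highest_r2_wins(self):
        best = self._fit("spherical", 0.694, 0.0078)
        other = self._fit("gaussian", 0.550, 0.1090)
        assert select_model([other, best]) is best

    def test_rss_breaks_r2_ties(self):
        a = self._fit("gaussian", 0.6, 0.0078)
        b = self._fit("exponential", 0.6, 0.0164)
        assert select_model([b, a]) is a

    def test_family_order_breaks_full_ties(self):
        a = self._fit("spherical", 0.6, 0.01)
        b = self._fit("linear", 0.6, 0.01)
        assert select_model([b, a]) is a

    def test_empty_rejected(self):
        with pytest.raises(VariogramError):
            select_model([])
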