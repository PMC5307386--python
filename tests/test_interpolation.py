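"""Ordinary kriging, IDW, grid prediction and the log back-transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socmap import (GridSpec, VariogramFit, back_transform, fit_trend_surface,
                    generate_locations, idw_predict, ok_predict, predict_grid,
                    simulate_gaussian_field)

DOMAIN = (0.0, 0.0, 40_000.0, 70_000.0)
FIT = VariogramFit("spherical", 0.04, 0.13, 20_000.0)


def random_samples(seed, n=10, scale=10_000.0):
    r = np.random.default_rng(seed)
    return r.uniform(0, scale, (n, 2)), r.normal(50, 10, n)


def dense_ok_oracle(target, coords, values, fit):
    """Brute-force ordinary-kriging solve over the full sample set."""
    n = len(values)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = fit.gamma(d)
    A[:n, n] = A[n, :n] = 1.0
    b = np.append(fit.gamma(np.linalg.norm(coords - target, axis=1)), 1.0)
    sol = np.linalg.solve(A, b)
    return float(sol[:n] @ values), float(sol[:n] @ b[:n] + sol[n])


class TestOrdinaryKriging:
    def test_exact_at_sample_without_nugget(self):
        coords, values = random_samples(0)
        fit = VariogramFit("spherical", 0.0, 0.13, 20_000.0)
        est, var, _ = ok_predict(coords[3], coords, values, fit, m=None)
        assert est == pytest.approx(values[3], rel=1e-10)
        assert var == pytest.approx(0.0, abs=1e-10)

    def test_exact_at_sample_with_nugget(self):
        coords, values = random_samples(1)
        est, var, _ = ok_predict(coords[5], coords, values, FIT, m=None)
        assert est == pytest.approx(values[5], rel=1e-10)
        assert var == pytest.approx(0.0, abs=1e-10)

    def test_pure_nugget_gives_equal_weights(self):
        coords, values = random_samples(2, n=8)
        fit = VariogramFit("spherical", 0.1, 0.1, 20_000.0)  # C = 0
        est, _, w = ok_predict((5_000.0, 5_000.0), coords, values, fit, m=8)
        np.testing.assert_allclose(w, 1.0 / 8, rtol=1e-10)
        assert est == pytest.approx(values.mean(), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        coords, values = random_samples(seed, n=10)
        target = np.array([4_000.0, 6_000.0])
        est, var, _ = ok_predict(target, coords, values, FIT, m=10)
        oest, ovar = dense_ok_oracle(target, coords, values, FIT)
        assert est == pytest.approx(oest, rel=1e-8)
        assert var == pytest.approx(ovar, rel=1e-8, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_weights_sum_to_one(self, seed):
        coords, values = random_samples(seed, n=30)
        r = np.random.default_rng(100 + seed)
        for _ in range(10):
            target = r.uniform(0, 10_000.0, 2)
            _, _, w = ok_predict(target, coords, values, FIT, m=16)
            assert abs(w.sum() - 1.0) < 1e-10

    def test_translation_equivariance(self):
        coords, values = random_samples(3, n=20)
        target = (2_000.0, 3_000.0)
        a, _, _ = ok_predict(target, coords, values, FIT, m=10)
        b, _, _ = ok_predict(target, coords, values + 77.0, FIT, m=10)
        assert b == pytest.approx(a + 77.0, rel=1e-10)

    def test_duplicate_samples_averaged(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1_000.0, 0.0],
                           [0.0, 1_000.0]])
        values = np.array([10.0, 20.0, 30.0, 40.0])
        est, _, _ = ok_predict((0.0, 0.0), coords, values, FIT, m=None)
        assert est == pytest.approx(15.0)  # average of the duplicates

    def test_variance_grows_along_empty_corridor(self):
        coords, values = random_samples(4, n=15, scale=5_000.0)
        vars_ = [ok_predict((6_000.0 + d, 6_000.0), coords, values, FIT,
                            m=None)[1] for d in (0, 3_000.0, 8_000.0)]
        assert vars_[0] < vars_[1] < vars_[2]


class TestIDW:
    def test_equidistant_neighbours_average(self):
        coords = np.array([[-100.0, 0.0], [100.0, 0.0]])
        assert idw_predict((0.0, 0.0), coords, [10.0, 30.0], power=1.0,
                           m=2) == pytest.approx(20.0)

    def test_coincident_target_returns_sample(self):
        coords, values = random_samples(5)
        assert idw_predict(coords[2], coords, values) == values[2]

    def test_single_neighbour_is_nearest_neighbour(self):
        coords, values = random_samples(6)
        target = (1_234.0, 5_678.0)
        d = np.linalg.norm(coords - target, axis=1)
        assert idw_predict(target, coords, values, m=1) == pytest.approx(
            values[d.argmin()], rel=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 1000), st.floats(0.5, 4.0))
    def test_convex_combination(self, seed, power):
        coords, values = random_samples(seed, n=12)
        est = idw_predict((3_000.0, 3_000.0), coords, values, power=power,
                          m=8)
        assert values.min() - 1e-9 <= est <= values.max() + 1e-9


class TestBackTransform:
    def test_zero_variance_is_plain_exp(self):
        assert back_transform(1.5, 0.0) == pytest.approx(np.exp(1.5))

    def test_lognormal_correction_closed_form(self):
        assert back_transform(0.0, 2.0 * np.log(2.0)) == pytest.approx(2.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            back_transform(0.0, 0.0, mode="median")


class TestPredictGrid:
    SPEC = GridSpec(origin=(0.0, 0.0), cell_size=1_000.0, nx=8, ny=8)

    def test_constant_samples_give_constant_grid(self):
        coords, _ = random_samples(7, n=20, scale=8_000.0)
        values = np.full(20, 55.0)
        for method in ("OK", "IDW"):
            grid = predict_grid(coords, values, self.SPEC, method=method,
                                fit=FIT)
            np.testing.assert_allclose(grid.prediction, 55.0, rtol=1e-9)

    def test_nugget_free_ok_honours_sample_on_cell_centre(self):
        r = np.random.default_rng(8)
        coords = r.uniform(0, 8_000.0, (15, 2))
        coords[0] = [2_500.0, 3_500.0]  # a cell centre of SPEC
        values = r.normal(50, 10, 15)
        fit = VariogramFit("spherical", 0.0, 0.13, 20_000.0)
        grid = predict_grid(coords, values, self.SPEC, method="OK", fit=fit)
        assert grid.prediction[3, 2] == pytest.approx(values[0], rel=1e-8)

    def test_mask_respected(self):
        coords, values = random_samples(9, n=20, scale=8_000.0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4, :] = True
        spec = GridSpec(origin=(0.0, 0.0), cell_size=1_000.0, nx=8, ny=8,
                        mask=mask)
        grid = predict_grid(coords, values, spec, method="IDW")
        assert np.isfinite(grid.prediction[mask]).all()
        assert np.isnan(grid.prediction[~mask]).all()

    def test_ok_and_idw_maps_agree_on_smooth_field(self):
        pts = generate_locations(120, (0, 0, 20_000.0, 20_000.0), 0.3, seed=3)
        truth = VariogramFit("spherical", 0.01, 0.2, 15_000.0)
        z = 50.0 + 20.0 * simulate_gaussian_field(pts, truth, seed=3)
        spec = GridSpec(origin=(0.0, 0.0), cell_size=1_000.0, nx=20, ny=20)
        ok = predict_grid(pts, z, spec, method="OK", fit=truth)
        idw = predict_grid(pts, z, spec, method="IDW")
        r = np.corrcoef(ok.prediction.ravel(), idw.prediction.ravel())[0, 1]
        assert r > 0.8

    def test_lognormal_pipeline_mean_nearly_unbiased(self):
        """Kriging a log-normal field on the log scale and back-transforming
        with the lognormal correction should roughly preserve the mean."""
        pts = generate_locations(150, (0, 0, 20_000.0, 20_000.0), 0.0, seed=6)
        truth = VariogramFit("spherical", 0.02, 0.12, 12_000.0)
        stocks = np.exp(4.0 + simulate_gaussian_field(pts, truth, seed=6))
        spec = GridSpec(origin=(0.0, 0.0), cell_size=1_000.0, nx=20, ny=20)
        trend = fit_trend_surface(pts, np.log(stocks))
        grid = predict_grid(pts, stocks, spec, method="OK", fit=truth,
                            log_transform=True, trend=trend)
        assert grid.prediction.mean() == pytest.approx(stocks.mean(),
                                                       rel=0.10)
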