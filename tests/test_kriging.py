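"""Semivariogram estimation, spherical fitting, ordinary kriging."""

import numpy as np
import pytest

from esvgrid import (EmpiricalVariogram, GaussianFieldSpec,
                     empirical_semivariogram, fit_spherical,
                     generate_gaussian_field, log_transform,
                     ordinary_kriging, spherical)
from esvgrid.kriging import VariogramModel

from conftest import kriging_dense_oracle, semivariogram_brute


def grid_points(n, spacing=1000.0):
    x, y = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    return np.column_stack([x.ravel(), y.ravel()])


class TestEmpiricalVariogram:
    def test_constant_field_zero_everywhere(self):
        pts = grid_points(5)
        emp = empirical_semivariogram(pts, np.full(25, 7.0), bin_width=1000.0)
        assert np.all(emp.gamma == 0.0)

    def test_two_point_hand_value(self):
        emp = empirical_semivariogram([[0, 0], [3000, 0]], [0.0, 2.0],
                                      bin_width=4000.0, max_lag=4000.0)
        assert len(emp.gamma) == 1
        assert emp.gamma[0] == pytest.approx(2.0)  # (2^2) / (2*1)
        assert emp.counts[0] == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10_000, size=(30, 2))
        vals = rng.normal(size=30)
        bw, ml = 1500.0, 9000.0
        emp = empirical_semivariogram(pts, vals, bin_width=bw, max_lag=ml)
        oracle, counts = semivariogram_brute(pts, vals, bw, ml)
        got = {int(h // bw): g for h, g in zip(emp.lags, emp.gamma)}
        assert set(got) == set(oracle)
        for b in oracle:
            assert got[b] == pytest.approx(oracle[b], abs=1e-12)

    def test_log_flag_and_zero_handling(self):
        pts = grid_points(4)
        vals = np.linspace(0.0, 3.0, 16)
        with pytest.warns(UserWarning, match="offset"):
            logged, offset = log_transform(vals)
        assert offset == pytest.approx(0.1)  # half the smallest positive
        assert logged[0] == pytest.approx(np.log(0.1))
        with pytest.raises(ValueError):
            log_transform(np.array([-1.0, 2.0]))


class TestSphericalFit:
    def test_noise_free_curve_recovered_exactly(self):
        h = np.arange(1, 15) * 500.0
        truth = dict(nugget=0.12, partial_sill=0.88, range_=4200.0)
        emp = EmpiricalVariogram(h, spherical(h, **truth),
                                 np.full(len(h), 50), 500.0, h.max())
        m = fit_spherical(emp)
        assert m.nugget == pytest.approx(truth["nugget"], abs=1e-6)
        assert m.partial_sill == pytest.approx(truth["partial_sill"], abs=1e-6)
        assert m.range_ == pytest.approx(truth["range_"], abs=1e-2)
        assert m.r2 == pytest.approx(1.0, abs=1e-9)
        assert m.rss == pytest.approx(0.0, abs=1e-12)
        assert m.nugget_effect_pct == pytest.approx(12.0, abs=1e-4)

    def test_range_recovery_from_simulated_fields(self):
        # truth: c0=0.1, c=0.9, a=5.5 km on a 100x100 grid of 1-km cells
        truth_range = 5500.0
        fitted = []
        for seed in range(20):
            f = generate_gaussian_field(GaussianFieldSpec(
                (100, 100), pixel_size=1000.0, nugget=0.1, partial_sill=0.9,
                range_=truth_range, seed=seed))
            emp = empirical_semivariogram(grid_points(100), f.ravel(),
                                          bin_width=1000.0, max_lag=15_000.0)
            fitted.append(fit_spherical(emp).range_)
        assert abs(np.mean(fitted) - truth_range) / truth_range < 0.20

    def test_too_few_bins_rejected(self):
        emp = EmpiricalVariogram(np.array([1.0, 2.0, 3.0]),
                                 np.array([0.1, 0.2, 0.3]),
                                 np.array([5, 5, 5]), 1.0, 3.0)
        with pytest.raises(ValueError, match="bins"):
            fit_spherical(emp)


MODEL = VariogramModel(nugget=0.0, partial_sill=1.0, range_=5000.0,
                       r2=1.0, rss=0.0)


class TestOrdinaryKriging:
    def test_single_point_prediction(self):
        preds, _ = ordinary_kriging(MODEL, [[0.0, 0.0]], [4.2],
                                    [[500.0, 500.0], [9e3, 9e3]])
        assert np.allclose(preds, 4.2)

    def test_midpoint_between_two_points_is_symmetric(self):
        preds, _, wts = ordinary_kriging(
            MODEL, [[0.0, 0.0], [2000.0, 0.0]], [1.0, 3.0], [[1000.0, 0.0]],
            return_weights=True)
        idx, w = wts[0]
        assert np.allclose(sorted(w), [0.5, 0.5], atol=1e-10)
        assert preds[0] == pytest.approx(2.0)

    def test_weights_sum_to_one_everywhere(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10_000, size=(40, 2))
        vals = rng.normal(size=40)
        targets = rng.uniform(0, 10_000, size=(25, 2))
        _, _, wts = ordinary_kriging(MODEL, pts, vals, targets,
                                     n_neighbors=10, return_weights=True)
        for _, w in wts:
            assert np.sum(w) == pytest.approx(1.0, abs=1e-10)

    def test_exact_interpolation_with_zero_nugget(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 8000, size=(30, 2))
        vals = rng.normal(size=30)
        preds, var = ordinary_kriging(MODEL, pts, vals, pts, n_neighbors=16)
        assert np.allclose(preds, vals, atol=1e-8)
        assert np.all(var >= 0)
        assert np.allclose(var, 0.0, atol=1e-8)

    def test_matches_dense_solve_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 5000, size=(5, 2))
        vals = rng.normal(size=5)
        model = VariogramModel(nugget=0.2, partial_sill=0.8, range_=3000.0,
                               r2=1.0, rss=0.0)
        targets = rng.uniform(0, 5000, size=(7, 2))
        preds, _ = ordinary_kriging(model, pts, vals, targets, n_neighbors=16)
        for t, xy in enumerate(targets):
            oracle_pred, oracle_w = kriging_dense_oracle(model, pts, vals, xy)
            assert preds[t] == pytest.approx(oracle_pred, abs=1e-10)
            assert oracle_w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_constant_data_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5000, size=(20, 2))
        preds, _ = ordinary_kriging(MODEL, pts, np.full(20, 2.5),
                                    rng.uniform(0, 5000, size=(10, 2)),
                                    n_neighbors=8)
        assert np.allclose(preds, 2.5, atol=1e-10)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ordinary_kriging(MODEL, [[0, 0], [0, 0], [1, 1]], [1, 2, 3],
                             [[0.5, 0.5]])

    def test_zero_sill_rejected(self):
        bad = VariogramModel(0.0, 0.0, 1000.0, 1.0, 0.0)
        with pytest.raises(ValueError, match="sill"):
            ordinary_kriging(bad, [[0, 0], [1, 1]], [1, 2], [[0.5, 0.5]])
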