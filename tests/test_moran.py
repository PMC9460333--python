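"""Global, local and bivariate Moran's I against brute-force oracles."""

import numpy as np
import pytest

from esvgrid import (LisaResult, bivariate_moran, build_weights,
                     classify_clusters, global_moran, local_moran,
                     moran_scatter_data)
from esvgrid.moran import MoranResult

from conftest import bivariate_moran_brute, lattice_grid, moran_brute


def checkerboard(n_rows, n_cols):
    r, c = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    return np.where((r + c) % 2 == 0, 1.0, -1.0).ravel()


class TestWeights:
    def test_neighbor_counts_on_full_lattice(self):
        grid = lattice_grid(5, 5)
        q = build_weights(grid, "queen", row_standardize=False)
        r = build_weights(grid, "rook", row_standardize=False)
        interior = 2 * 5 + 2  # (row 2, col 2)
        assert len(q.neighbors[interior]) == 8
        assert len(r.neighbors[interior]) == 4
        assert len(q.neighbors[0]) == 3  # corner, queen

    def test_row_standardized_rows_sum_to_one(self):
        w = build_weights(lattice_grid(4, 6), "queen", row_standardize=True)
        sums = np.asarray(w.matrix.sum(axis=1)).ravel()
        assert np.allclose(sums, 1.0)
        assert w.s0 == pytest.approx(w.n)

    def test_l_shaped_set_matches_hand_enumeration(self):
        # cells: (0,0),(1,0),(2,0),(2,1),(2,2) — an L
        keep = {(0, 0), (1, 0), (2, 0), (2, 1), (2, 2)}
        drop = {(r, c) for r in range(3) for c in range(3)} - keep
        grid = lattice_grid(3, 3, drop=drop)
        w = build_weights(grid, "queen", row_standardize=False)
        idx = {(r, c): i for i, (r, c) in
               enumerate(zip(grid["row"], grid["col"]))}
        expected = {
            (0, 0): {(1, 0)},
            (1, 0): {(0, 0), (2, 0), (2, 1)},
            (2, 0): {(1, 0), (2, 1)},
            (2, 1): {(1, 0), (2, 0), (2, 2)},
            (2, 2): {(2, 1)},
        }
        for rc, nbs in expected.items():
            got = {tuple(grid.iloc[j][["row", "col"]]) for j in
                   w.neighbors[idx[rc]]}
            assert got == nbs, rc

    def test_symmetry_before_standardization(self):
        grid = lattice_grid(4, 4, drop={(1, 1), (2, 3)})
        w = build_weights(grid, "queen", row_standardize=False)
        m = w.matrix.toarray()
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            build_weights(lattice_grid(1, 1))


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        grid = lattice_grid(4, 4)
        w = build_weights(grid, "rook", row_standardize=True)
        res = global_moran(checkerboard(4, 4), w, n_permutations=99, seed=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_permutation_null_mean_matches_expectation(self):
        grid = lattice_grid(2, 5)
        w = build_weights(grid, "rook")
        x = np.random.default_rng(1).normal(size=10)
        res = global_moran(x, w, n_permutations=999, seed=5)
        assert res.expected == pytest.approx(-1 / 9)
        assert res.perm_mean == pytest.approx(-1 / 9, abs=0.03)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("scheme,std", [("queen", True), ("rook", False)])
    def test_matches_brute_force_double_sum(self, seed, scheme, std):
        rng = np.random.default_rng(seed)
        drop = {(int(r), int(c)) for r, c in
                rng.integers(0, 6, size=(8, 2))}
        grid = lattice_grid(6, 6, drop=drop)
        w = build_weights(grid, scheme, row_standardize=std)
        x = rng.normal(size=len(grid))
        res = global_moran(x, w, n_permutations=19, seed=0)
        assert res.I == pytest.approx(moran_brute(x, w), abs=1e-12)

    def test_constant_input_rejected(self):
        w = build_weights(lattice_grid(3, 3))
        with pytest.raises(ValueError, match="constant"):
            global_moran(np.ones(9), w)

    def test_fixed_seed_reproducible(self):
        w = build_weights(lattice_grid(5, 5))
        x = np.random.default_rng(0).normal(size=25)
        a = global_moran(x, w, n_permutations=99, seed=11)
        b = global_moran(x, w, n_permutations=99, seed=11)
        assert a.p_value == b.p_value and a.z_score == b.z_score

    def test_pseudo_p_null_calibration(self):
        # The directional pseudo-p picks its tail from the observed
        # statistic, so under an i.i.d. null the valid guarantee is
        # P(p <= t) <= 2t (each fixed tail alone is >= uniform); the +1
        # numerator keeps p >= 1/(M+1) always.
        grid = lattice_grid(5, 5)
        w = build_weights(grid, "queen")
        rng = np.random.default_rng(123)
        n_reps, n_perm = 200, 199
        ps = np.array([
            global_moran(rng.normal(size=25), w, n_permutations=n_perm,
                         seed=int(rng.integers(2 ** 31))).p_value
            for _ in range(n_reps)])
        assert ps.min() >= 1 / (n_perm + 1)
        for t in [0.01, 0.05, 0.10, 0.25, 0.50]:
            frac = np.mean(ps <= t)
            slack = 3 * np.sqrt(2 * t * (1 - 2 * t if t < 0.5 else 1)
                                / n_reps) + 1 / (n_perm + 1)
            assert frac <= 2 * t + slack, (t, frac)


class TestLocalMoran:
    def test_mean_local_equals_global(self):
        grid = lattice_grid(7, 7)
        w = build_weights(grid, "queen", row_standardize=True)
        x = np.random.default_rng(3).normal(size=49)
        lisa = local_moran(x, w, n_permutations=49, seed=0)
        assert lisa.local_I.mean() == pytest.approx(
            lisa.global_result.I, abs=1e-10)

    def test_hot_spot_block_labelled_high_high(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0.0, 0.1, size=(10, 10))
        vals[3:6, 3:6] += 10.0  # planted 3x3 hot spot
        grid = lattice_grid(10, 10)
        w = build_weights(grid, "queen")
        lisa = local_moran(vals.ravel(), w, n_permutations=999, seed=1)
        block = [r * 10 + c for r in range(3, 6) for c in range(3, 6)]
        labels = lisa.labels[block]
        assert (labels == "H-H").sum() >= 5
        assert lisa.labels[3 * 10 + 4] == "H-H"  # inner block row

    def test_checkerboard_all_negative_quadrants(self):
        grid = lattice_grid(6, 6)
        w = build_weights(grid, "rook")
        lisa = local_moran(checkerboard(6, 6), w, n_permutations=99, seed=0)
        assert set(lisa.quadrant) <= {"H-L", "L-H"}

    def test_isolate_gets_nan_p_and_ns_label(self):
        grid = lattice_grid(9, 9, drop={(r, c) for r in range(9)
                                        for c in range(9)
                                        if 2 < max(abs(r - 8), abs(c - 8))
                                        and (r, c) != (0, 0)})
        w = build_weights(grid, "queen")
        assert len(w.isolates) == 1
        x = np.random.default_rng(2).normal(size=len(grid))
        lisa = local_moran(x, w, n_permutations=49, seed=0)
        iso = w.isolates[0]
        assert np.isnan(lisa.p_value[iso])
        assert lisa.labels[iso] == "ns"


class TestBivariateMoran:
    def test_reduces_to_univariate_when_y_equals_x(self):
        grid = lattice_grid(6, 6)
        w = build_weights(grid, "queen")
        x = np.random.default_rng(4).normal(size=36)
        biv, _ = bivariate_moran(x, x, w, n_permutations=19, seed=0)
        uni = global_moran(x, w, n_permutations=19, seed=0)
        assert biv.I == pytest.approx(uni.I, abs=1e-12)
        bneg, _ = bivariate_moran(x, -x, w, n_permutations=19, seed=0)
        assert bneg.I == pytest.approx(-uni.I, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        grid = lattice_grid(5, 7, drop={(0, 0), (4, 6), (2, 3)})
        w = build_weights(grid, "queen")
        x = rng.normal(size=len(grid))
        y = rng.normal(size=len(grid))
        biv, _ = bivariate_moran(x, y, w, n_permutations=19, seed=0)
        assert biv.I == pytest.approx(bivariate_moran_brute(x, y, w),
                                      abs=1e-12)

    def test_anticorrelated_smooth_fields_negative(self):
        from esvgrid import GaussianFieldSpec, generate_gaussian_field
        f = generate_gaussian_field(GaussianFieldSpec(
            (12, 12), pixel_size=1000.0, nugget=0.0, partial_sill=1.0,
            range_=6000.0, seed=6))
        rng = np.random.default_rng(6)
        x = f.ravel()
        y = -f.ravel() + rng.normal(0, 0.1, size=144)
        grid = lattice_grid(12, 12)
        w = build_weights(grid, "queen")
        biv, _ = bivariate_moran(x, y, w, n_permutations=99, seed=0)
        assert biv.I < 0

    def test_length_mismatch_rejected(self):
        w = build_weights(lattice_grid(3, 3))
        with pytest.raises(ValueError, match="length"):
            bivariate_moran(np.arange(9.0), np.arange(8.0), w)


class TestClassification:
    @staticmethod
    def _lisa(p, quadrant):
        n = len(p)
        glob = MoranResult(0.1, -0.1, 1.0, 0.5, n, 99, 0, 0.0, 1.0)
        return LisaResult(np.zeros(n), np.array(quadrant, dtype=object),
                          np.array(p), np.array(["ns"] * n, dtype=object),
                          0.05, glob)

    def test_all_insignificant(self):
        lisa = self._lisa([1.0, 1.0], ["H-H", "L-L"])
        out = classify_clusters(lisa)
        assert (out["cluster"] == "ns").all()

    def test_significance_tiers(self):
        lisa = self._lisa([0.02, 0.005, 0.2], ["H-L", "L-H", "H-H"])
        out = classify_clusters(lisa)
        assert out["cluster"].tolist() == ["H-L (p<0.05)", "L-H (p<0.01)",
                                           "ns"]

    def test_spillover_fixture_interface_bands(self):
        # a high-x block adjacent to a high-y block plants H-L/L-H structure
        x = np.zeros((8, 8))
        y = np.zeros((8, 8))
        x[:, :4] = 5.0   # high land-use degree, west half
        y[:, 4:] = 5.0   # high service value, east half
        rng = np.random.default_rng(9)
        x += rng.normal(0, 0.1, x.shape)
        y += rng.normal(0, 0.1, y.shape)
        grid = lattice_grid(8, 8)
        w = build_weights(grid, "queen")
        _, lisa = bivariate_moran(x.ravel(), y.ravel(), w,
                                  n_permutations=999, seed=0)
        out = classify_clusters(lisa)
        sig = out[out["cluster"] != "ns"]
        assert not sig.empty
        assert set(sig["quadrant"]) <= {"H-L", "L-H"}


def test_moran_scatter_slope_equals_I():
    grid = lattice_grid(8, 8)
    w = build_weights(grid, "queen", row_standardize=True)
    x = np.random.default_rng(5).normal(size=64)
    sc = moran_scatter_data(x, w)
    slope = np.polyfit(sc["z"], sc["lag_z"], 1)[0]
    uni = global_moran(x, w, n_permutations=19, seed=0)
    assert slope == pytest.approx(uni.I, abs=1e-10)
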