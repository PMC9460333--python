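"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (explicit double
sums, dense linear solves, per-pair loops) and independent of the package
code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def block_fixture():
    from esvgrid import make_fixture
    return make_fixture()


def lattice_grid(n_rows: int, n_cols: int, drop: set[tuple[int, int]] = frozenset()
                 ) -> pd.DataFrame:
    """Minimal grid table (row, col, cell_id, S) for weights-building tests."""
    recs = [
        {"cell_id": r * n_cols + c, "row": r, "col": c, "S_km2": 1.0}
        for r in range(n_rows) for c in range(n_cols)
        if (r, c) not in drop
    ]
    df = pd.DataFrame.from_records(recs)
    df.attrs["fishnet"] = {"cell_size": 1000.0, "cell_px": 1, "n_rows": n_rows,
                           "n_cols": n_cols, "origin": (0.0, 0.0),
                           "pixel_size": 1000.0,
                           "raster_shape": (n_rows, n_cols)}
    return df


def dense_weight_matrix(w) -> np.ndarray:
    """Dense W rebuilt from the neighbour lists (not from w.matrix)."""
    n = w.n
    mat = np.zeros((n, n))
    for i, (nb, wt) in enumerate(zip(w.neighbors, w.weights)):
        for j, v in zip(nb, wt):
            mat[i, j] = v
    return mat


def moran_brute(x: np.ndarray, w) -> float:
    """Global Moran's I by explicit double sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    z = x - x.mean()
    mat = dense_weight_matrix(w)
    s0 = mat.sum()
    num = sum(mat[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / s0 * num / float((z ** 2).sum())


def bivariate_moran_brute(x: np.ndarray, y: np.ndarray, w) -> float:
    """Bivariate Moran's I by explicit double sum over standardized values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    mat = dense_weight_matrix(w)
    n = len(x)
    num = sum(mat[i, j] * zx[i] * zy[j] for i in range(n) for j in range(n))
    return num / mat.sum()


def semivariogram_brute(points: np.ndarray, values: np.ndarray,
                        bin_width: float, max_lag: float):
    """Per-pair loop semivariogram estimate; returns dict bin-index -> gamma."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(points[i] - points[j])))
            if d > max_lag or d == 0:
                continue
            b = min(int(d // bin_width), int(np.ceil(max_lag / bin_width)) - 1)
            sums[b] = sums.get(b, 0.0) + (values[i] - values[j]) ** 2
            counts[b] = counts.get(b, 0) + 1
    return {b: sums[b] / (2 * counts[b]) for b in sums}, counts


def kriging_dense_oracle(gamma_fn, points: np.ndarray, values: np.ndarray,
                         target: np.ndarray):
    """Full-matrix ordinary-kriging solve; returns (prediction, weights)."""
    n = len(points)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            a[i, j] = gamma_fn(np.hypot(*(points[i] - points[j])))
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    b = np.array([gamma_fn(np.hypot(*(p - target))) for p in points] + [1.0])
    sol = np.linalg.solve(a, b)
    return float(sol[:n] @ values), sol[:n]
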