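"""Empirical semivariograms, spherical-model fitting, ordinary kriging.

The workflow mirrors classical geostatistical practice on gridded
ecosystem-service intensity: (optionally log-transform the intensity,)
estimate the empirical semivariogram

    gamma_hat(h) = 1 / (2 |N(h)|) * sum_{(i,j) in N(h)} (z_i - z_j)^2

over distance bins, fit the spherical model

    gamma(h) = c0 + c * (1.5 h/a - 0.5 (h/a)^3)   for 0 < h <= a
    gamma(h) = c0 + c                              for h > a,   gamma(0) = 0

by pair-count-weighted nonlinear least squares (nugget c0, partial sill c,
range a; the nugget effect c0/(c0+c)*100 summarizes how much variance is
unstructured), and interpolate by ordinary kriging — the best linear
unbiased predictor whose weights solve the semivariance system with a
Lagrange multiplier enforcing sum(w) = 1. The model is evaluated with
gamma(0) = 0, so kriging is an exact interpolator at the data locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "empirical_semivariogram",
    "spherical",
    "fit_spherical",
    "ordinary_kriging",
    "log_transform",
]


@dataclass
class EmpiricalVariogram:
    lags: np.ndarray          # bin centers (same length units as points)
    gamma: np.ndarray         # semivariance estimate per bin
    counts: np.ndarray        # pair counts per bin
    bin_width: float
    max_lag: float
    log_transformed: bool = False


@dataclass
class VariogramModel:
    """Fitted spherical model with diagnostics against the binned estimates."""

    nugget: float
    partial_sill: float
    range_: float
    r2: float
    rss: float
    model: str = "spherical"

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def nugget_effect_pct(self) -> float:
        return 100.0 * self.nugget / self.sill if self.sill > 0 else np.nan

    def __call__(self, h) -> np.ndarray:
        return spherical(h, self.nugget, self.partial_sill, self.range_)


def spherical(h, nugget: float, partial_sill: float, range_: float):
    """Spherical semivariogram; gamma(0) = 0 by convention."""
    h = np.asarray(h, dtype=float)
    r = np.clip(h / range_, 0.0, 1.0)
    g = nugget + partial_sill * (1.5 * r - 0.5 * r ** 3)
    return np.where(h > 0, g, 0.0)


def log_transform(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Natural log of a non-negative intensity, offsetting exact zeros.

    Zeros are replaced by half the smallest positive value before logging
    (with a warning); returns the logged values and the offset used (0.0
    when no zeros were present). Negative inputs are rejected.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("log transform requires non-negative values")
    offset = 0.0
    if (values == 0).any():
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("cannot log-transform an all-zero field")
        offset = 0.5 * positive.min()
        warnings.warn(f"zero intensities offset by {offset:g} before logging")
        values = np.where(values == 0, offset, values)
    return np.log(values), offset


def empirical_semivariogram(points, values, bin_width: float,
                            max_lag: float | None = None,
                            log: bool = False) -> EmpiricalVariogram:
    """Binned isotropic semivariogram estimate over all pairs within max_lag.

    ``points`` is (n, 2) coordinates; ``max_lag`` defaults to half the
    diagonal of the point bounding box. Empty bins are dropped with a
    warning. With ``log=True`` the values are natural-log transformed first
    (non-positive values handled by :func:`log_transform`).
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) != len(vals):
        raise ValueError("points must be (n, 2) matching values")
    if len(pts) < 2:
        raise ValueError("need at least 2 points for a semivariogram")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    if log:
        vals, _ = log_transform(vals)
    if max_lag is None:
        span = pts.max(axis=0) - pts.min(axis=0)
        max_lag = 0.5 * float(np.hypot(*span))
    tree = cKDTree(pts)
    pairs = tree.query_pairs(max_lag, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("no point pairs within max_lag")
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    sq = (vals[pairs[:, 0]] - vals[pairs[:, 1]]) ** 2
    nbins = max(1, int(np.ceil(max_lag / bin_width)))
    which = np.minimum((d / bin_width).astype(np.int64), nbins - 1)
    counts = np.bincount(which, minlength=nbins)
    sums = np.bincount(which, weights=sq, minlength=nbins)
    centers = (np.arange(nbins) + 0.5) * bin_width
    keep = counts > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} empty lag bins")
    gamma = sums[keep] / (2.0 * counts[keep])
    return EmpiricalVariogram(centers[keep], gamma, counts[keep],
                              bin_width, max_lag, log_transformed=log)


def fit_spherical(emp: EmpiricalVariogram) -> VariogramModel:
    """Fit the spherical model by pair-count-weighted least squares.

    Residuals are weighted by sqrt(pair count); parameters are bounded at
    zero (clipping negative estimates, with a warning when the optimizer
    pushes against the bound from an unstructured input). R² and RSS are
    reported unweighted against the binned estimates.
    """
    h, g, cnt = emp.lags, emp.gamma, emp.counts
    if len(h) < 4:
        raise ValueError("need at least 4 non-empty bins to fit")
    wt = np.sqrt(cnt.astype(float))
    gmax = g.max()
    if gmax == 0:  # constant field: degenerate but well-defined
        return VariogramModel(0.0, 0.0, float(h.max()), 1.0, 0.0)

    def resid(theta):
        c0, c, a = theta
        return (spherical(h, c0, c, a) - g) * wt

    x0 = np.array([max(g[0], 1e-10 * gmax),
                   max(gmax - g[0], 1e-10 * gmax),
                   0.5 * float(h.max())])
    sol = least_squares(resid, x0, bounds=([0, 0, 1e-12 * h.max()],
                                           [np.inf, np.inf, np.inf]))
    if not sol.success:
        raise RuntimeError(f"spherical fit did not converge: {sol.message}; "
                           f"best iterate {sol.x}")
    c0, c, a = sol.x
    pred = spherical(h, c0, c, a)
    rss = float(np.sum((pred - g) ** 2))
    tss = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return VariogramModel(float(c0), float(c), float(a), r2, rss)


def ordinary_kriging(model: VariogramModel, points, values, targets,
                     n_neighbors: int = 16, return_weights: bool = False):
    """Ordinary-kriging prediction and variance at target locations.

    Per target, the ``n_neighbors`` nearest data points (all points when
    k >= n) enter the semivariance system

        [Gamma  1] [w ]   [gamma_t]
        [1ᵀ     0] [mu] = [1      ]

    whose solution gives prediction wᵀ·values and kriging variance
    wᵀ·gamma_t + mu. Duplicate data locations are rejected. Returns
    ``(predictions, variances)``; with ``return_weights=True`` additionally
    a list of ``(data_indices, weights)`` per target.
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    if model.sill <= 0:
        raise ValueError("kriging requires a positive sill")
    if len(pts) == 0:
        raise ValueError("no data points")
    if len(pts) > 1:
        tree = tree_all = cKDTree(pts)
        if len(tree_all.query_pairs(1e-9)) > 0:
            raise ValueError("duplicate data locations; deduplicate first")
    else:
        tree = None
    k = min(n_neighbors, len(pts))
    preds = np.empty(len(tgt))
    variances = np.empty(len(tgt))
    weights_out: list[tuple[np.ndarray, np.ndarray]] = []
    for t, xy in enumerate(tgt):
        if len(pts) == 1:
            preds[t] = vals[0]
            variances[t] = 2.0 * float(model(np.linalg.norm(xy - pts[0])))
            weights_out.append((np.array([0]), np.array([1.0])))
            continue
        _, idx = tree.query(xy, k=k)
        idx = np.atleast_1d(idx)
        local = pts[idx]
        m = len(idx)
        dmat = np.linalg.norm(local[:, None, :] - local[None, :, :], axis=-1)
        a = np.empty((m + 1, m + 1))
        a[:m, :m] = model(dmat)
        a[m, :m] = a[:m, m] = 1.0
        a[m, m] = 0.0
        b = np.empty(m + 1)
        b[:m] = model(np.linalg.norm(local - xy, axis=1))
        b[m] = 1.0
        sol = np.linalg.solve(a, b)
        w, mu = sol[:m], sol[m]
        preds[t] = float(w @ vals[idx])
        variances[t] = max(float(w @ b[:m] + mu), 0.0)
        weights_out.append((idx, w))
    if return_weights:
        return preds, variances, weights_out
    return preds, variances
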