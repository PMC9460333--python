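"""Global, local (LISA) and bivariate Moran's I with permutation inference.

All statistics are computed from first principles on lattice contiguity
weights built from the fishnet's (row, col) indexing:

* global Moran's I
      I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
  with S0 = sum_ij w_ij; under the spatial-randomness null E[I] = -1/(n-1).
* local Moran's I (Anselin's LISA)
      I_i = ((x_i - xbar) / m2) * sum_j w_ij (x_j - xbar),   m2 = sum (x-xbar)^2 / n
  whose mean over cells equals the global I under row-standardized weights
  (population variance scaling makes the identity exact).
* bivariate Moran's I — the cross-product of one standardized variable with
  the spatial lag of another (GeoDa convention, population scaling):
      I_xy = (1 / S0) * sum_ij w_ij zx_i zy_j,  local I_xy,i = zx_i * lag(zy)_i.

Inference is purely by permutation: the global statistics permute the whole
value vector; the local statistics use conditional permutation (the focal
value is held fixed, the remaining n-1 values are drawn without replacement
into the neighbour slots). Pseudo p-values follow the GeoDa convention
p = (k + 1) / (M + 1) with k the number of permuted statistics at least as
extreme as the observed one in the observed tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "LisaResult",
    "build_weights",
    "global_moran",
    "local_moran",
    "bivariate_moran",
    "classify_clusters",
    "moran_scatter_data",
]

_QUEEN = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_ROOK = [(-1, 0), (0, -1), (0, 1), (1, 0)]


@dataclass
class SpatialWeights:
    """Contiguity weights over the retained fishnet cells.

    ``neighbors[i]`` holds positional indices (into the grid-table order) of
    cell i's neighbours; ``weights[i]`` the matching weights. ``matrix`` is
    the same information as a CSR sparse matrix for fast spatial lags.
    Isolates (retained cells with no retained neighbour) keep empty lists
    and are reported in ``isolates``.
    """

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    row_standardized: bool
    scheme: str
    matrix: sparse.csr_matrix = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())

    @property
    def isolates(self) -> np.ndarray:
        return np.flatnonzero([len(nb) == 0 for nb in self.neighbors])

    def lag(self, z: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(z, dtype=float)


def build_weights(grid: pd.DataFrame, scheme: str = "queen",
                  row_standardize: bool = True) -> SpatialWeights:
    """Queen (8-neighbour) or rook (4-neighbour) lattice contiguity.

    Adjacency is evaluated on the fishnet (row, col) lattice restricted to
    the retained cells; binary weights are optionally row-standardized to
    sum to 1 per row (GeoDa's default convention).
    """
    offsets = {"queen": _QUEEN, "rook": _ROOK}.get(scheme)
    if offsets is None:
        raise ValueError(f"unknown contiguity scheme {scheme!r}")
    rows = grid["row"].to_numpy()
    cols = grid["col"].to_numpy()
    n = len(grid)
    if n < 2:
        raise ValueError("need at least two cells to build weights")
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}
    neighbors, weights = [], []
    for r, c in zip(rows, cols):
        nb = [index[(r + dr, c + dc)] for dr, dc in offsets
              if (r + dr, c + dc) in index]
        nb = np.array(sorted(nb), dtype=np.int64)
        if row_standardize and len(nb):
            w = np.full(len(nb), 1.0 / len(nb))
        else:
            w = np.ones(len(nb))
        neighbors.append(nb)
        weights.append(w)
    indptr = np.cumsum([0] + [len(nb) for nb in neighbors])
    indices = np.concatenate(neighbors) if n else np.empty(0, dtype=np.int64)
    data = np.concatenate(weights)
    mat = sparse.csr_matrix((data, indices, indptr), shape=(n, n))
    return SpatialWeights(neighbors, weights, row_standardize, scheme, mat)


@dataclass
class MoranResult:
    I: float
    expected: float
    z_score: float
    p_value: float
    n: int
    n_permutations: int
    seed: int | None
    perm_mean: float
    perm_std: float


@dataclass
class LisaResult:
    """Per-cell local Moran output plus the matching global summary."""

    local_I: np.ndarray
    quadrant: np.ndarray        # strings from {"H-H","L-L","H-L","L-H"}
    p_value: np.ndarray
    labels: np.ndarray          # quadrant if p < alpha else "ns"
    alpha: float
    global_result: MoranResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "local_I": self.local_I, "quadrant": self.quadrant,
            "p_value": self.p_value, "label": self.labels,
        })


def _check_values(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError(f"{name} is constant; Moran's I is undefined")
    return x


def _pseudo_p(observed: float, perms: np.ndarray, center: float) -> float:
    """One-tailed pseudo p in the observed tail, (k+1)/(M+1)."""
    if observed >= center:
        k = int(np.sum(perms >= observed))
    else:
        k = int(np.sum(perms <= observed))
    return (k + 1) / (len(perms) + 1)


def global_moran(x, w: SpatialWeights, n_permutations: int = 999,
                 seed: int | None = None) -> MoranResult:
    """Global Moran's I with full-vector permutation inference."""
    x = _check_values(x)
    n = w.n
    if len(x) != n:
        raise ValueError("x length does not match weights")
    if n < 3:
        raise ValueError("need n >= 3")
    z = x - x.mean()
    denom = float(z @ z)
    s0 = w.s0
    stat = lambda zv: n / s0 * float(zv @ w.lag(zv)) / denom
    i_obs = stat(z)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for k in range(n_permutations):
        perms[k] = stat(rng.permutation(z))
    p = _pseudo_p(i_obs, perms, expected)
    pm, ps = float(perms.mean()), float(perms.std())
    zsc = (i_obs - pm) / ps if ps > 0 else np.nan
    return MoranResult(i_obs, expected, zsc, p, n, n_permutations, seed, pm, ps)


def _quadrants(z_focal: np.ndarray, lag: np.ndarray) -> np.ndarray:
    hi = z_focal > 0
    lag_hi = lag > 0
    out = np.where(hi & lag_hi, "H-H",
                   np.where(~hi & ~lag_hi, "L-L",
                            np.where(hi & ~lag_hi, "H-L", "L-H")))
    return out.astype(object)


def _conditional_permutation(values: np.ndarray, w: SpatialWeights,
                             focal_factor: np.ndarray, n_permutations: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Permutation distribution of ``focal_factor_i * lag_i`` per cell.

    ``values`` are the numbers permuted into the neighbour slots (the n-1
    values excluding the focal cell); ``focal_factor`` multiplies the
    permuted lag (z_i/m2 for the univariate LISA, zx_i for the bivariate).
    Returns an (n, n_permutations) array of permuted local statistics.
    """
    n = w.n
    k_max = max((len(nb) for nb in w.neighbors), default=0)
    # each row: a fresh draw without replacement of k_max positions among n-1
    draws = np.argsort(rng.random((n_permutations, n - 1)), axis=1)[:, :k_max]
    out = np.zeros((n, n_permutations))
    for i in range(n):
        nb = w.neighbors[i]
        if len(nb) == 0:
            out[i] = np.nan
            continue
        others = np.delete(values, i)
        sample = others[draws[:, :len(nb)]]          # (nperm, k_i)
        lag_p = sample @ w.weights[i]
        out[i] = focal_factor[i] * lag_p
    return out


def _local_p(obs: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Per-cell one-tailed pseudo p against each cell's permuted mean."""
    n, m = perms.shape
    p = np.empty(n)
    for i in range(n):
        if np.isnan(perms[i]).any():
            p[i] = np.nan  # isolate: no permutation distribution
            continue
        p[i] = _pseudo_p(obs[i], perms[i], float(perms[i].mean()))
    return p


def local_moran(x, w: SpatialWeights, n_permutations: int = 999,
                seed: int | None = None, alpha: float = 0.05) -> LisaResult:
    """Anselin's local Moran's I with conditional permutation inference."""
    x = _check_values(x)
    if len(x) != w.n:
        raise ValueError("x length does not match weights")
    z = x - x.mean()
    m2 = float(z @ z) / len(z)
    lag = w.lag(z)
    local = (z / m2) * lag
    rng = np.random.default_rng(seed)
    perms = _conditional_permutation(z, w, z / m2, n_permutations, rng)
    p = _local_p(local, perms)
    quad = _quadrants(z, lag)
    labels = np.where(p < alpha, quad, "ns").astype(object)
    glob = global_moran(x, w, n_permutations=n_permutations, seed=seed)
    return LisaResult(local, quad, p, labels, alpha, glob)


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()  # population scaling
    return (v - v.mean()) / s


def bivariate_moran(x, y, w: SpatialWeights, n_permutations: int = 999,
                    seed: int | None = None,
                    alpha: float = 0.05) -> tuple[MoranResult, LisaResult]:
    """Bivariate Moran's I: x against the spatial lag of y.

    Both variables are standardized to zero mean and unit (population)
    variance. Global inference permutes y against the fixed x; local
    inference conditionally permutes y into each cell's neighbour slots.
    """
    x = _check_values(x, "x")
    y = _check_values(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    if len(x) != w.n:
        raise ValueError("variable length does not match weights")
    zx, zy = _standardize(x), _standardize(y)
    n, s0 = w.n, w.s0
    stat = lambda zyv: float(zx @ w.lag(zyv)) / s0
    i_obs = stat(zy)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for k in range(n_permutations):
        perms[k] = stat(rng.permutation(zy))
    p = _pseudo_p(i_obs, perms, float(perms.mean()))
    pm, ps = float(perms.mean()), float(perms.std())
    zsc = (i_obs - pm) / ps if ps > 0 else np.nan
    glob = MoranResult(i_obs, 0.0, zsc, p, n, n_permutations, seed, pm, ps)

    lag_zy = w.lag(zy)
    local = zx * lag_zy
    perms_loc = _conditional_permutation(zy, w, zx, n_permutations, rng)
    p_loc = _local_p(local, perms_loc)
    quad = _quadrants(zx, lag_zy)
    labels = np.where(p_loc < alpha, quad, "ns").astype(object)
    lisa = LisaResult(local, quad, p_loc, labels, alpha, glob)
    return glob, lisa


def classify_clusters(lisa: LisaResult,
                      alphas: tuple[float, ...] = (0.05, 0.01)) -> pd.DataFrame:
    """Label cells by quadrant and significance tier.

    With the default tiers a cell significant at 0.01 is labelled e.g.
    ``"H-L (p<0.01)"``, one significant only at 0.05 ``"H-L (p<0.05)"``,
    anything else ``"ns"``.
    """
    tiers = sorted(alphas)  # most stringent first
    labels = np.full(len(lisa.local_I), "ns", dtype=object)
    for a in sorted(tiers, reverse=True):  # loosest first, overwritten by tighter
        hit = lisa.p_value < a
        labels[hit] = [f"{q} (p<{a:g})" for q in lisa.quadrant[hit]]
    return pd.DataFrame({
        "local_I": lisa.local_I, "quadrant": lisa.quadrant,
        "p_value": lisa.p_value, "cluster": labels,
    })


def moran_scatter_data(x, w: SpatialWeights) -> pd.DataFrame:
    """Standardized values vs their spatial lag (the Moran scatterplot).

    With row-standardized weights the least-squares slope of lag on z
    equals the global Moran's I.
    """
    x = _check_values(x)
    z = _standardize(x)
    return pd.DataFrame({"z": z, "lag_z": w.lag(z)})
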