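"""Synthetic landscapes and Gaussian random fields with known structure.

Real basin land-use maps come from supervised classification of satellite
imagery and cannot be redistributed; every downstream stage of the pipeline
is therefore exercised against neutral-landscape surrogates generated here:

* :func:`generate_landscape` — a categorical map built by rank-thresholding
  a smoothed Gaussian field, so class proportions are controlled exactly and
  spatial clumping is governed by a single ``aggregation`` knob;
* :func:`generate_gaussian_field` — a stationary random field whose
  semivariogram is a known spherical model (nugget + partial sill + range),
  used for variogram/kriging parameter-recovery tests;
* :func:`make_fixture` — a tiny hand-specified block landscape whose
  per-cell area table is known in closed form, used as an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import LandscapeRaster

__all__ = [
    "SyntheticSpec",
    "GaussianFieldSpec",
    "DEFAULT_PROPORTIONS",
    "generate_landscape",
    "generate_gaussian_field",
    "make_fixture",
]

#: Default 10-class composition of the synthetic basin. The first-level
#: totals (urban 4.13%, cropland 27.20%, grassland 36.2%, woodland 28.51%,
#: unutilized 3.07%, water+wetland 0.89%) follow the study basin; the
#: second-level splits within grassland, woodland and water/wetland are
#: package choices documented in docs/methods.md.
DEFAULT_PROPORTIONS: dict[int, float] = {
    1: 0.2720,   # cropland
    2: 0.0500,   # forestland
    3: 0.2351,   # other forestland (shrub)
    4: 0.1500,   # high-coverage grassland
    5: 0.1300,   # medium-coverage grassland
    6: 0.0820,   # low-coverage grassland
    7: 0.0070,   # water
    8: 0.0019,   # wetland
    9: 0.0413,   # urban
    10: 0.0307,  # unutilized
}


@dataclass
class SyntheticSpec:
    """Recipe for one categorical landscape."""

    grid_shape: tuple[int, int]
    pixel_size: float = 10.0
    class_proportions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    aggregation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.aggregation < 0:
            raise ValueError("aggregation must be >= 0")
        props = self.class_proportions
        if not props:
            raise ValueError("class_proportions must be non-empty")
        for code, p in props.items():
            if not isinstance(code, (int, np.integer)) or code <= 0:
                raise ValueError(f"invalid class code {code!r} (0 is nodata)")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for class {code} outside [0, 1]")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1 (tol 1e-9)")


@dataclass
class GaussianFieldSpec:
    """Spherical-variogram Gaussian field: nugget c0, partial sill c, range a."""

    grid_shape: tuple[int, int]
    pixel_size: float = 1000.0
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_: float = 5500.0
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be positive")


def _allocate_counts(proportions: dict[int, float], n: int) -> dict[int, int]:
    """Integer pixel counts per class: largest-remainder apportionment of n."""
    codes = sorted(proportions)
    exact = np.array([proportions[c] * n for c in codes])
    counts = np.floor(exact).astype(np.int64)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:short]] += 1
    return dict(zip(codes, counts))


def generate_landscape(spec: SyntheticSpec) -> LandscapeRaster:
    """Rank-threshold a smoothed Gaussian field into class codes.

    One standard-normal field is smoothed with a Gaussian kernel of
    ``sigma = aggregation`` pixels (0 means independent pixels), then pixels
    are sorted by field value and assigned to classes in ascending class-code
    order at the cumulative target proportions. Pixel counts per class equal
    ``round(target * N)`` within +/-1 (largest-remainder rounding), so
    empirical proportions are exact up to integer resolution at any
    aggregation level; clumping grows with ``aggregation``.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    fieldv = rng.standard_normal((rows, cols))
    if spec.aggregation > 0:
        fieldv = ndimage.gaussian_filter(fieldv, sigma=spec.aggregation,
                                         mode="wrap")
    flat = fieldv.ravel()
    order = np.argsort(flat, kind="stable")
    counts = _allocate_counts(spec.class_proportions, flat.size)
    out = np.empty(flat.size, dtype=np.int64)
    start = 0
    for code in sorted(counts):
        k = counts[code]
        out[order[start:start + k]] = code
        start += k
    values = out.reshape(rows, cols)
    meta = {"generator": "rank-thresholded smoothed Gaussian",
            "aggregation": spec.aggregation, "seed": spec.seed}
    return LandscapeRaster(values, spec.pixel_size, meta=meta)


def spherical_covariance(h: np.ndarray, partial_sill: float,
                         range_: float) -> np.ndarray:
    """Covariance implied by the spherical variogram (no nugget term)."""
    h = np.asarray(h, dtype=float)
    r = np.clip(h / range_, 0.0, 1.0)
    return partial_sill * (1.0 - 1.5 * r + 0.5 * r ** 3)


def generate_gaussian_field(spec: GaussianFieldSpec) -> np.ndarray:
    """Simulate a stationary field with spherical covariance + nugget.

    Uses circulant embedding on a doubled torus: the target covariance is
    laid out over wrapped lattice distances, diagonalized by FFT, and any
    (small) negative eigenvalues from an imperfect embedding are clamped to
    zero. The independent nugget component is added as white noise.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    out = np.full((rows, cols), float(spec.mean))
    if spec.partial_sill > 0:
        m, n = 2 * rows, 2 * cols
        di = np.minimum(np.arange(m), m - np.arange(m))
        dj = np.minimum(np.arange(n), n - np.arange(n))
        h = np.hypot(di[:, None], dj[None, :]) * spec.pixel_size
        cov = spherical_covariance(h, spec.partial_sill, spec.range_)
        lam = np.fft.fft2(cov).real
        lam = np.maximum(lam, 0.0)
        noise = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
        sim = np.fft.fft2(np.sqrt(lam / (m * n)) * noise)
        out += sim.real[:rows, :cols]
    if spec.nugget > 0:
        out += np.sqrt(spec.nugget) * rng.standard_normal((rows, cols))
    return out


# --- deterministic block fixture -------------------------------------------

#: fixture geometry: 300x300 px of 10 m = 3x3 km, 1-km cells -> 3x3 fishnet
_FIX_SHAPE = (300, 300)
_FIX_PIXEL = 10.0
_FIX_CELL_PX = 100


def make_fixture() -> tuple[LandscapeRaster, np.ndarray, pd.DataFrame]:
    """Small deterministic landscape with an exactly known area table.

    Returns ``(raster, mask, expected)``. The 3x3 km landscape is built from
    1-km class blocks: the western column is cropland, the middle column is
    split half cropland / half water within each cell, the eastern column is
    urban over unutilized over high-coverage grassland. The mask removes the
    south-east corner cell's lower half (so that cell has S_j = 0.5 km²) and
    one full-cell notch is left entirely outside the mask in the north-east.

    ``expected`` has one row per retained cell with columns ``row``, ``col``,
    ``S_km2`` and ``A_<code>`` — computed here from the block layout, not by
    the gridding code, so it can serve as an independent oracle.
    """
    rows, cols = _FIX_SHAPE
    v = np.zeros(_FIX_SHAPE, dtype=np.int64)
    c = _FIX_CELL_PX
    # west column: cropland
    v[:, :c] = 1
    # middle column: in every cell, north half cropland, south half water
    for cr in range(3):
        v[cr * c:cr * c + c // 2, c:2 * c] = 1
        v[cr * c + c // 2:(cr + 1) * c, c:2 * c] = 7
    # east column: urban / unutilized / high-coverage grassland
    v[0:c, 2 * c:] = 9
    v[c:2 * c, 2 * c:] = 10
    v[2 * c:, 2 * c:] = 4

    mask = np.ones(_FIX_SHAPE, dtype=bool)
    mask[0:c, 2 * c:] = False          # NE corner cell wholly outside
    mask[2 * c + c // 2:, 2 * c:] = False  # SE cell: lower half clipped

    half = 0.5
    records = []
    layout = {
        (0, 0): {1: 1.0}, (0, 1): {1: half, 7: half},
        (1, 0): {1: 1.0}, (1, 1): {1: half, 7: half}, (1, 2): {10: 1.0},
        (2, 0): {1: 1.0}, (2, 1): {1: half, 7: half}, (2, 2): {4: half},
    }
    for (r_, c_), areas in sorted(layout.items()):
        rec = {"row": r_, "col": c_, "S_km2": sum(areas.values())}
        for code, a in areas.items():
            rec[f"A_{code}"] = a
        records.append(rec)
    expected = pd.DataFrame.from_records(records).fillna(0.0)
    raster = LandscapeRaster(v, _FIX_PIXEL, meta={"generator": "block fixture"})
    return raster, mask, expected
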