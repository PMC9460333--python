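"""Fishnet gridding, per-cell class-area tabulation, accuracy metrics.

The fishnet is a regular square tessellation (1 x 1 km by default) snapped
to the raster's upper-left origin. All areas are obtained by pixel counting
on the native raster — exact integer arithmetic times the pixel area — never
by polygon overlay. Cells intersecting at least one valid (masked-in,
non-nodata) pixel are retained; edge cells keep their true covered area
S_j < 1 km², which the valuation stage later corrects through the intensity
ESV_j / S_j.

The grid is carried as a pandas DataFrame ("GridTable"): one row per
retained cell with columns ``cell_id``, ``row``, ``col``, ``S_km2`` and,
after tabulation, one dense ``A_<code>`` area column (km²) per scheme class.
Fishnet geometry metadata lives in ``df.attrs``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import LandscapeRaster

__all__ = [
    "build_fishnet",
    "tabulate_class_areas",
    "area_columns",
    "cell_polygons",
    "confusion_matrix_metrics",
]


def _valid_mask(raster: LandscapeRaster, mask) -> np.ndarray:
    valid = raster.valid_mask()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != raster.shape:
            raise ValueError("mask shape does not match raster shape")
        valid &= mask
    if not valid.any():
        raise ValueError("mask excludes every valid pixel")
    return valid


def _cell_index(raster: LandscapeRaster, cell_size: float):
    """Per-pixel fishnet (row, col) and the fishnet dimensions."""
    ratio = cell_size / raster.pixel_size
    cell_px = int(round(ratio))
    if abs(ratio - cell_px) > 1e-9 or cell_px < 1:
        raise ValueError(
            f"cell_size {cell_size} is not an integer multiple of "
            f"pixel_size {raster.pixel_size}")
    rows, cols = raster.shape
    n_rows = -(-rows // cell_px)
    n_cols = -(-cols // cell_px)
    crow = np.arange(rows) // cell_px
    ccol = np.arange(cols) // cell_px
    return crow, ccol, n_rows, n_cols, cell_px


def build_fishnet(raster: LandscapeRaster, mask=None,
                  cell_size: float = 1000.0,
                  min_coverage: float = 0.0) -> pd.DataFrame:
    """Build the fishnet grid table over the masked raster.

    Parameters
    ----------
    mask : optional boolean array (True = inside the study area) with the
        raster's shape; combined with the raster's own nodata mask.
    cell_size : fishnet cell edge in metres; must be an integer multiple of
        the pixel size.
    min_coverage : drop cells whose covered fraction S_j / nominal area is
        *at or below* this threshold (default 0 keeps every cell touching a
        valid pixel; edge cells are retained with partial S_j).
    """
    valid = _valid_mask(raster, mask)
    crow, ccol, n_rows, n_cols, cell_px = _cell_index(raster, cell_size)
    flat_cell = crow[:, None] * n_cols + ccol[None, :]
    counts = np.bincount(flat_cell[valid], minlength=n_rows * n_cols)
    pixel_area = raster.pixel_area_km2
    s = counts * pixel_area
    nominal = (cell_size / 1000.0) ** 2
    keep = (counts > 0) & (s / nominal > min_coverage) if min_coverage > 0 \
        else counts > 0
    cell_ids = np.flatnonzero(keep)
    df = pd.DataFrame({
        "cell_id": cell_ids,
        "row": cell_ids // n_cols,
        "col": cell_ids % n_cols,
        "S_km2": s[keep],
    })
    df.attrs["fishnet"] = {
        "cell_size": float(cell_size), "cell_px": cell_px,
        "n_rows": int(n_rows), "n_cols": int(n_cols),
        "origin": tuple(raster.origin), "pixel_size": float(raster.pixel_size),
        "raster_shape": tuple(raster.shape),
    }
    return df


def tabulate_class_areas(raster: LandscapeRaster, grid: pd.DataFrame,
                         mask=None, codes=None) -> pd.DataFrame:
    """Add per-class area columns A_<code> (km²) to the grid table.

    The class list defaults to the codes present in the raster; pass the
    scheme's codes for a dense table with explicit zero columns. Areas are
    pixel counts times pixel area, so ``sum(A_ij) == S_j`` exactly.
    """
    meta = grid.attrs.get("fishnet")
    if meta is None:
        raise ValueError("grid has no fishnet metadata")
    if (meta["raster_shape"] != tuple(raster.shape)
            or meta["pixel_size"] != raster.pixel_size
            or meta["origin"] != tuple(raster.origin)):
        raise ValueError("raster geometry does not match the fishnet grid")
    valid = _valid_mask(raster, mask)
    crow, ccol, n_rows, n_cols, _ = _cell_index(raster, meta["cell_size"])
    flat_cell = (crow[:, None] * n_cols + ccol[None, :])[valid]
    vals = raster.values[valid]
    if codes is None:
        codes = np.unique(vals)
    codes = np.asarray(sorted(int(c) for c in codes))
    code_pos = {c: i for i, c in enumerate(codes)}
    unknown = set(np.unique(vals)) - set(code_pos)
    if unknown:
        raise ValueError(f"raster codes {sorted(unknown)} missing from class list")
    pos = np.vectorize(code_pos.__getitem__, otypes=[np.int64])(vals)
    combo = flat_cell * len(codes) + pos
    counts = np.bincount(combo, minlength=n_rows * n_cols * len(codes))
    counts = counts.reshape(n_rows * n_cols, len(codes))[grid["cell_id"].to_numpy()]
    areas = counts * raster.pixel_area_km2
    out = grid.copy()
    out.attrs = dict(grid.attrs)
    for i, c in enumerate(codes):
        out[f"A_{c}"] = areas[:, i]
    return out


def area_columns(grid: pd.DataFrame) -> dict[int, str]:
    """Map class code -> area column name for a tabulated grid."""
    return {int(col[2:]): col for col in grid.columns if col.startswith("A_")}


def cell_polygons(grid: pd.DataFrame) -> list[list[tuple[float, float]]]:
    """Exterior rings (map units, closed, CCW) of every retained cell."""
    meta = grid.attrs["fishnet"]
    cs = meta["cell_size"]
    x0, y0 = meta["origin"]
    rings = []
    for r, c in zip(grid["row"], grid["col"]):
        x, y = x0 + c * cs, y0 - r * cs
        rings.append([(x, y - cs), (x + cs, y - cs), (x + cs, y), (x, y),
                      (x, y - cs)])
    return rings


def confusion_matrix_metrics(matrix, labels=None) -> dict:
    """Accuracy metrics from a confusion matrix of pixel/sample counts.

    Orientation convention: **rows are the mapped class, columns the
    reference class**, so producer accuracy (omission side) is column-wise
    and user accuracy (commission side) is row-wise.

    Returns a dict with overall accuracy ``OA``, ``kappa``, and per-class
    ``PA`` / ``UA`` keyed by label; classes with an empty reference column
    (or empty mapped row) get ``nan`` and are listed under ``undefined``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any() or not np.allclose(m, np.round(m)):
        raise ValueError("confusion matrix must hold non-negative counts")
    total = m.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    if labels is None:
        labels = list(range(m.shape[0]))
    diag = np.diag(m)
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    oa = diag.sum() / total
    pe = float(row @ col) / total ** 2
    kappa = (oa - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(col > 0, diag / np.where(col > 0, col, 1), np.nan)
        ua = np.where(row > 0, diag / np.where(row > 0, row, 1), np.nan)
    undefined = [lab for lab, r_, c_ in zip(labels, row, col) if r_ == 0 or c_ == 0]
    return {
        "OA": float(oa),
        "kappa": float(kappa),
        "PA": dict(zip(labels, pa.tolist())),
        "UA": dict(zip(labels, ua.tolist())),
        "undefined": undefined,
    }
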