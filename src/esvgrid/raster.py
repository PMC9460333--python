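"""Raster containers and plain-text (ESRI ASCII grid) I/O.

All rasters live in a single projected CRS with coordinates in metres.
``LandscapeRaster`` holds integer land-use class codes; continuous fields
(Gaussian simulations, kriging output) are plain 2-D float arrays carried
with the same georeferencing convention: ``origin`` is the (x, y) of the
*upper-left corner* of the upper-left pixel, rows increase southwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: class code reserved for "no data" in integer rasters
NODATA = 0


@dataclass
class LandscapeRaster:
    """Categorical land-use raster.

    Parameters
    ----------
    values : (rows, cols) integer array of class codes; ``nodata`` marks
        pixels outside the study area.
    pixel_size : pixel edge length in metres.
    origin : (x0, y0) map coordinates of the upper-left corner.
    nodata : reserved code for invalid pixels (default 0).
    meta : free-form provenance (seed, generator spec, ...).
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = NODATA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("landscape raster must hold integer class codes")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size / 1000.0) ** 2

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def class_codes(self) -> np.ndarray:
        """Sorted codes present in the raster, excluding nodata."""
        codes = np.unique(self.values)
        return codes[codes != self.nodata]

    def xy_of_pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of every pixel center, as 1-D x and y axes."""
        rows, cols = self.shape
        x0, y0 = self.origin
        x = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        y = y0 - (np.arange(rows) + 0.5) * self.pixel_size
        return x, y


def write_ascii_grid(path, values: np.ndarray, pixel_size: float,
                     origin: tuple[float, float] = (0.0, 0.0),
                     nodata=NODATA, fmt: str | None = None) -> None:
    """Write a 2-D array as an ESRI ASCII grid (.asc).

    The header records the lower-left corner as the format requires;
    ``origin`` is still upper-left, converted here.
    """
    values = np.asarray(values)
    rows, cols = values.shape
    x0, y0 = origin
    yll = y0 - rows * pixel_size
    if fmt is None:
        fmt = "%d" if np.issubdtype(values.dtype, np.integer) else "%.10g"
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner {x0:.6f}\nyllcorner {yll:.6f}\n"
        f"cellsize {pixel_size:.6f}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Read an ESRI ASCII grid; returns (values, pixel_size, origin_ul, nodata)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA_value line absent
                break
        fh.seek(pos)
        values = np.loadtxt(fh)
    rows = int(header["nrows"])
    cols = int(header["ncols"])
    values = values.reshape(rows, cols)
    pixel_size = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + rows * pixel_size)
    nodata = header.get("nodata_value", NODATA)
    return values, pixel_size, origin, nodata


def read_landscape(path, scheme=None) -> LandscapeRaster:
    """Read a categorical .asc raster, optionally validating codes.

    ``scheme`` may be a :class:`~esvgrid.valuation.ClassScheme`; any code in
    the raster absent from the scheme raises ``ValueError`` naming the code
    and its pixel count.
    """
    values, pixel_size, origin, nodata = read_ascii_grid(path)
    ivalues = values.astype(np.int64)
    if not np.array_equal(ivalues, values):
        raise ValueError(f"{path}: non-integer values in categorical raster")
    raster = LandscapeRaster(ivalues, pixel_size, origin, nodata=int(nodata))
    if scheme is not None:
        known = set(scheme.codes) | {raster.nodata}
        codes, counts = np.unique(ivalues, return_counts=True)
        bad = [(int(c), int(n)) for c, n in zip(codes, counts) if c not in known]
        if bad:
            desc = ", ".join(f"code {c} ({n} px)" for c, n in bad)
            raise ValueError(f"{path}: unknown class codes: {desc}")
    return raster


def write_landscape(path, raster: LandscapeRaster) -> None:
    write_ascii_grid(path, raster.values, raster.pixel_size, raster.origin,
                     nodata=raster.nodata)


def rasterize_polygon_mask(geometry, shape: tuple[int, int], pixel_size: float,
                           origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside a polygon.

    ``geometry`` is a shapely geometry or a GeoJSON-like mapping.
    """
    import shapely
    from shapely.geometry import shape as shp_shape

    if isinstance(geometry, dict):
        if geometry.get("type") == "FeatureCollection":
            geoms = [shp_shape(f["geometry"]) for f in geometry["features"]]
            geometry = shapely.unary_union(geoms)
        elif geometry.get("type") == "Feature":
            geometry = shp_shape(geometry["geometry"])
        else:
            geometry = shp_shape(geometry)
    rows, cols = shape
    x0, y0 = origin
    x = x0 + (np.arange(cols) + 0.5) * pixel_size
    y = y0 - (np.arange(rows) + 0.5) * pixel_size
    xx, yy = np.meshgrid(x, y)
    return shapely.contains_xy(geometry, xx.ravel(), yy.ravel()).reshape(shape)
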