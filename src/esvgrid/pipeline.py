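"""End-to-end pipeline runner, run configuration, and table/report I/O.

One :func:`run_pipeline` call executes the whole grid-scale analysis in
order — fishnet gridding, class-area tabulation, land-use degree and ESV
valuation, global/local Moran's I of the degree index and of ESV intensity,
bivariate Moran's I between the two, then variogram fitting and ordinary
kriging of (log) ESV intensity — and writes every artifact under the
configured output directory:

* ``grid.csv``             the grid table with all derived columns
* ``grid.geojson``         cell polygons with the same attributes
* ``summary_by_class.csv`` per-class ESV totals and shares
* ``clusters_*.csv``       LISA cluster tables
* ``kriged_intensity.asc`` the interpolated surface (plain-text raster)
* ``report.json``          global statistics, parameter echo, stage timings

Every output embeds the run seed, the class-scheme checksum and the package
version, so a report suffices to rerun the analysis exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grid import build_fishnet, tabulate_class_areas, cell_polygons
from .kriging import empirical_semivariogram, fit_spherical, ordinary_kriging, \
    log_transform
from .moran import build_weights, local_moran, bivariate_moran, classify_clusters
from .raster import LandscapeRaster, read_landscape, rasterize_polygon_mask, \
    read_ascii_grid, write_ascii_grid
from .synthetic import SyntheticSpec, generate_landscape
from .valuation import ClassScheme, load_default_scheme, esv_coefficients, \
    add_valuation_columns, summarize_by_class, correction_coefficient, \
    unit_equivalent_value

__all__ = ["RunConfig", "run_pipeline", "write_grid", "read_grid",
           "write_grid_geojson", "write_report"]


@dataclass
class RunConfig:
    """Everything needed to rerun one analysis exactly."""

    output_dir: str = "esvgrid_out"
    # input: either a raster path or a synthetic block (dict of SyntheticSpec
    # fields); mask is an optional .asc path or GeoJSON path
    landscape_path: str | None = None
    mask_path: str | None = None
    synthetic: dict | None = None
    scheme_path: str | None = None          # None -> packaged default scheme
    cell_size: float = 1000.0
    # valuation: explicit E_esv wins; otherwise computed from the yields
    e_esv: float | None = None
    national_unit_value: float | None = None
    regional_yield: float | None = None
    national_yield: float | None = None
    # autocorrelation
    weights_scheme: str = "queen"
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    # variogram / kriging
    variogram_bin_width: float | None = None   # default: cell size
    variogram_max_lag: float | None = None
    log_intensity: bool = True
    kriging_neighbors: int = 16
    kriging_factor: int = 1   # output grid refinement per fishnet cell

    def __post_init__(self) -> None:
        if self.landscape_path is None and self.synthetic is None:
            raise ValueError("config needs landscape_path or a synthetic block")
        for p in (self.landscape_path, self.mask_path, self.scheme_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def resolve_e_esv(self) -> float:
        from .valuation import PAPER_UNIT_EQUIVALENT_VALUE
        if self.e_esv is not None:
            return self.e_esv
        if self.national_unit_value is not None:
            ratio = correction_coefficient(self.regional_yield,
                                           self.national_yield)
            return unit_equivalent_value(self.national_unit_value, ratio)
        return PAPER_UNIT_EQUIVALENT_VALUE

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _float_fmt(x: float) -> str:
    return repr(float(x))


def write_grid(path, grid: pd.DataFrame, extra_meta: dict | None = None) -> None:
    """Grid table to CSV with the fishnet metadata in '#' header lines."""
    meta = {"fishnet": grid.attrs.get("fishnet", {}),
            "version": __version__}
    if extra_meta:
        meta.update(extra_meta)
    with open(path, "w") as fh:
        fh.write("# esvgrid " + json.dumps(meta, sort_keys=True) + "\n")
        grid.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_grid(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("# esvgrid "):
            meta = json.loads(first[len("# esvgrid "):])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    if "fishnet" in meta and meta["fishnet"]:
        fn = meta["fishnet"]
        for key in ("origin", "raster_shape"):
            if key in fn:
                fn[key] = tuple(fn[key])
        df.attrs["fishnet"] = fn
    return df


def write_grid_geojson(path, grid: pd.DataFrame,
                       properties: list[str] | None = None) -> None:
    """Cell polygons as a GeoJSON FeatureCollection (map units, no CRS tag)."""
    if properties is None:
        properties = [c for c in grid.columns if c != "cell_id"]
    rings = cell_polygons(grid)
    feats = []
    for (_, rec), ring in zip(grid.iterrows(), rings):
        props = {"cell_id": int(rec["cell_id"])}
        for c in properties:
            v = rec[c]
            props[c] = (float(v) if isinstance(v, (int, float, np.floating))
                        else v)
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Polygon",
                         "coordinates": [[list(xy) for xy in ring]]},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _load_inputs(config: RunConfig, scheme: ClassScheme):
    if config.synthetic is not None:
        spec_kwargs = dict(config.synthetic)
        spec_kwargs.setdefault("seed", config.seed)
        if "grid_shape" in spec_kwargs:
            spec_kwargs["grid_shape"] = tuple(spec_kwargs["grid_shape"])
        if "class_proportions" in spec_kwargs:
            spec_kwargs["class_proportions"] = {
                int(k): float(v)
                for k, v in spec_kwargs["class_proportions"].items()}
        raster = generate_landscape(SyntheticSpec(**spec_kwargs))
    else:
        raster = read_landscape(config.landscape_path, scheme=scheme)
    mask = None
    if config.mask_path is not None:
        p = Path(config.mask_path)
        if p.suffix.lower() in {".json", ".geojson"}:
            with open(p) as fh:
                geometry = json.load(fh)
            mask = rasterize_polygon_mask(geometry, raster.shape,
                                          raster.pixel_size, raster.origin)
        else:
            mvals, *_ = read_ascii_grid(p)
            mask = mvals.astype(bool)
    return raster, mask


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns the report dict (also written)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {"version": __version__, "seed": config.seed,
                    "config": {k: v for k, v in asdict(config).items()}}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}"
                                       ) from exc
        return _T()

    scheme = (ClassScheme.from_csv(config.scheme_path)
              if config.scheme_path else load_default_scheme())
    report["scheme_checksum"] = scheme.checksum()

    with stage("load"):
        raster, mask = _load_inputs(config, scheme)

    with stage("fishnet"):
        grid = build_fishnet(raster, mask=mask, cell_size=config.cell_size)
        grid = tabulate_class_areas(raster, grid, mask=mask,
                                    codes=scheme.codes)
    report["n_cells"] = int(len(grid))

    with stage("valuation"):
        e_esv = config.resolve_e_esv()
        coeffs = esv_coefficients(scheme, e_esv)
        grid = add_valuation_columns(grid, scheme, coeffs)
        summary = summarize_by_class(grid, scheme, coeffs)
        report["e_esv_cny_per_ha"] = float(e_esv)
        report["total_esv_cny"] = float(summary.loc[0, "esv_cny"])

    with stage("autocorrelation"):
        w = build_weights(grid, scheme=config.weights_scheme,
                          row_standardize=True)
        lisa_lu = local_moran(grid["L"].to_numpy(), w,
                              n_permutations=config.n_permutations,
                              seed=config.seed, alpha=config.alpha)
        lisa_esv = local_moran(grid["V_esv"].to_numpy(), w,
                               n_permutations=config.n_permutations,
                               seed=config.seed + 1, alpha=config.alpha)
        biv, lisa_biv = bivariate_moran(
            grid["L"].to_numpy(), grid["V_esv"].to_numpy(), w,
            n_permutations=config.n_permutations, seed=config.seed + 2,
            alpha=config.alpha)
        for key, res in (("moran_lu_degree", lisa_lu.global_result),
                         ("moran_esv_intensity", lisa_esv.global_result),
                         ("moran_bivariate", biv)):
            report[key] = {"I": res.I, "expected": res.expected,
                           "z_score": res.z_score, "p_value": res.p_value,
                           "n_permutations": res.n_permutations}
        report["n_isolates"] = int(len(w.isolates))

    with stage("variogram_kriging"):
        meta = grid.attrs["fishnet"]
        cs = meta["cell_size"]
        x0, y0 = meta["origin"]
        cx = x0 + (grid["col"].to_numpy() + 0.5) * cs
        cy = y0 - (grid["row"].to_numpy() + 0.5) * cs
        pts = np.column_stack([cx, cy])
        vals = grid["V_esv"].to_numpy()
        if config.log_intensity:
            vals, _ = log_transform(vals)
        bw = config.variogram_bin_width or cs
        too_small = len(grid) < 10
        if too_small:  # degenerate input: no estimable variogram
            import warnings
            warnings.warn("fewer than 10 cells: variogram/kriging skipped")
            report["variogram"] = None
            report["kriging"] = None
        else:
            emp = empirical_semivariogram(pts, vals, bin_width=bw,
                                          max_lag=config.variogram_max_lag)
            model = fit_spherical(emp)
            report["variogram"] = {
                "model": model.model, "nugget": model.nugget,
                "partial_sill": model.partial_sill, "sill": model.sill,
                "range_m": model.range_,
                "nugget_effect_pct": model.nugget_effect_pct,
                "r2": model.r2, "rss": model.rss,
                "log_transformed": bool(config.log_intensity),
            }
            f = max(1, int(config.kriging_factor))
            nr, nc = meta["n_rows"] * f, meta["n_cols"] * f
            step = cs / f
            gx = x0 + (np.arange(nc) + 0.5) * step
            gy = y0 - (np.arange(nr) + 0.5) * step
            gxx, gyy = np.meshgrid(gx, gy)
            targets = np.column_stack([gxx.ravel(), gyy.ravel()])
            preds, krig_var = ordinary_kriging(
                model, pts, vals, targets,
                n_neighbors=config.kriging_neighbors)
            surface = preds.reshape(nr, nc)
            write_ascii_grid(out / "kriged_intensity.asc", surface, step,
                             (x0, y0), nodata=-9999)
            if config.log_intensity:
                write_ascii_grid(out / "kriged_intensity_backtransformed.asc",
                                 np.exp(surface), step, (x0, y0), nodata=-9999)
            report["kriging"] = {
                "n_targets": int(len(targets)),
                "neighborhood": int(config.kriging_neighbors),
                "mean_variance": float(krig_var.mean()),
            }

    with stage("write"):
        run_meta = {"seed": config.seed,
                    "scheme_checksum": report["scheme_checksum"]}
        grid_out = grid.copy()
        grid_out.attrs = dict(grid.attrs)
        grid_out["lisa_lu_label"] = lisa_lu.labels
        grid_out["lisa_esv_label"] = lisa_esv.labels
        grid_out["lisa_bivariate_label"] = lisa_biv.labels
        write_grid(out / "grid.csv", grid_out, extra_meta=run_meta)
        write_grid_geojson(out / "grid.geojson", grid_out)
        with open(out / "summary_by_class.csv", "w") as fh:
            fh.write("# esvgrid " + json.dumps(run_meta, sort_keys=True) + "\n")
            summary.to_csv(fh, float_format="%.12g", lineterminator="\n")
        for nm, lisa in (("lu_degree", lisa_lu), ("esv_intensity", lisa_esv),
                         ("bivariate", lisa_biv)):
            tab = classify_clusters(lisa)
            tab.insert(0, "cell_id", grid["cell_id"].to_numpy())
            tab.to_csv(out / f"clusters_{nm}.csv", index=False,
                       float_format="%.12g", lineterminator="\n")

    report["timings_s"] = timings
    write_report(out / "report.json", report)
    return report
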