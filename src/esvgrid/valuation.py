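"""Land-use degree index and equivalent-factor ecosystem-service valuation.

The equivalent-factor method prices each land class through a vector of 11
dimensionless service equivalents EC_k (food production ... aesthetic
landscape), expressed relative to one standard unit of cropland food
production. A region's economic value of one equivalent, E_esv (CNY/ha), is
the national unit value scaled by the regional/national grain-yield ratio;
the per-class value coefficient is then

    C_i = (sum_k EC_k,i) * E_esv            [CNY/ha]

and a grid cell's value and intensity are

    ESV_j = sum_i A_ij * C_i                [CNY, areas in ha]
    V_esv,j = ESV_j / S_j                   [CNY/km²]

with the intensity correcting the underestimation of partially covered edge
cells. The land-use degree index is the area-weighted mean of per-class
human-disturbance weights P_i (urban 4, cropland 3, water/grass/wood/wetland
2, unutilized 1):

    L_j = sum_i A_ij * P_i / S_j.

Unit conventions: areas are carried in km² everywhere in the grid table and
converted to hectares (x100) only at the valuation boundary; intensities are
CNY per km² of actually covered area.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .grid import area_columns

__all__ = [
    "SERVICE_FUNCTIONS",
    "NATIONAL_UNIT_VALUE_CNY_PER_HA",
    "REGIONAL_GRAIN_YIELD_KG_PER_HA",
    "NATIONAL_GRAIN_YIELD_KG_PER_HA",
    "PAPER_UNIT_EQUIVALENT_VALUE",
    "ClassScheme",
    "EsvCoefficients",
    "load_default_scheme",
    "correction_coefficient",
    "unit_equivalent_value",
    "esv_coefficients",
    "lu_degree",
    "cell_esv",
    "add_valuation_columns",
    "summarize_by_class",
]

SERVICE_FUNCTIONS = (
    "food_production", "raw_material_production", "water_supply",
    "gas_regulation", "climate_regulation", "environment_purification",
    "hydrological_regulation", "soil_conservation", "nutrient_cycling",
    "biodiversity", "aesthetic_landscape",
)

# Published calibration constants for the study basin (2020):
# national economic value of one ESV equivalent, and the regional vs
# national grain yields whose ratio rescales it.
NATIONAL_UNIT_VALUE_CNY_PER_HA = 3406.50
REGIONAL_GRAIN_YIELD_KG_PER_HA = 3411.0
NATIONAL_GRAIN_YIELD_KG_PER_HA = 5734.0
#: E_esv as printed in the source study's equations (CNY/ha). The unrounded
#: product 3406.50 * 3411/5734 = 2026.43 differs in the last digit; the
#: printed constant is the default so published arithmetic reproduces.
PAPER_UNIT_EQUIVALENT_VALUE = 2026.38


@dataclass
class ClassScheme:
    """Land-class table: codes, names, degree weights, service equivalents.

    ``table`` is indexed by integer class code with a ``name`` column, a
    ``p_weight`` column (LU-degree weight P_i) and one column per service
    function holding the equivalents EC_k.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("name", "p_weight", *SERVICE_FUNCTIONS)
                   if c not in self.table.columns]
        if missing:
            raise ValueError(f"class scheme missing columns: {missing}")
        eq = self.table[list(SERVICE_FUNCTIONS)]
        if (eq.to_numpy() < 0).any():
            raise ValueError("service equivalents must be >= 0")

    @property
    def codes(self) -> list[int]:
        return [int(c) for c in self.table.index]

    @property
    def p_weights(self) -> pd.Series:
        return self.table["p_weight"].astype(float)

    def equivalents(self) -> pd.DataFrame:
        return self.table[list(SERVICE_FUNCTIONS)].astype(float)

    def total_equivalents(self) -> pd.Series:
        """Sum of the 11 equivalents per class (the multiplier of E_esv)."""
        return self.equivalents().sum(axis=1)

    def checksum(self) -> str:
        payload = self.table.round(10).to_csv().encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_csv(cls, path) -> "ClassScheme":
        df = pd.read_csv(path).set_index("code")
        return cls(df)


def load_default_scheme() -> ClassScheme:
    """The packaged 10-class scheme for the study basin (urban priced 0)."""
    ref = resources.files("esvgrid.data") / "esv_equivalents.csv"
    with resources.as_file(ref) as path:
        return ClassScheme.from_csv(path)


def correction_coefficient(regional_yield: float, national_yield: float) -> float:
    """Regional/national grain-yield ratio (unrounded; display rounds to 2 dp)."""
    if regional_yield <= 0 or national_yield <= 0:
        raise ValueError("grain yields must be positive")
    return regional_yield / national_yield


def unit_equivalent_value(national_unit_value: float, ratio: float) -> float:
    """Regional economic value of one equivalent, E_esv = unit value x ratio."""
    if national_unit_value <= 0 or ratio <= 0:
        raise ValueError("inputs must be positive")
    return national_unit_value * ratio


@dataclass
class EsvCoefficients:
    """Per-class value coefficients C_i (CNY/ha) at a given E_esv."""

    unit_equivalent_value: float
    per_class: pd.Series  # indexed by class code, CNY/ha

    def coefficient(self, code: int) -> float:
        return float(self.per_class.loc[code])


def esv_coefficients(scheme: ClassScheme,
                     e_esv: float = PAPER_UNIT_EQUIVALENT_VALUE) -> EsvCoefficients:
    """C_i = (sum of the class's 11 equivalents) x E_esv, CNY/ha."""
    if e_esv <= 0:
        raise ValueError("E_esv must be positive")
    per_class = scheme.total_equivalents() * e_esv
    return EsvCoefficients(unit_equivalent_value=e_esv, per_class=per_class)


def _areas_matrix(grid: pd.DataFrame, codes) -> np.ndarray:
    cols = area_columns(grid)
    missing = [c for c in codes if c not in cols]
    if missing:
        raise ValueError(f"grid lacks area columns for classes {missing}; "
                         "run tabulate_class_areas with the scheme codes")
    return grid[[cols[c] for c in codes]].to_numpy(dtype=float)


def lu_degree(grid: pd.DataFrame, scheme: ClassScheme) -> pd.Series:
    """Land-use degree L_j = sum_i A_ij P_i / S_j (dimensionless).

    For fully classified cells L_j lies within [min P_i, max P_i].
    Cells with S_j = 0 get NaN.
    """
    codes = scheme.codes
    a = _areas_matrix(grid, codes)
    p = scheme.p_weights.loc[codes].to_numpy(dtype=float)
    s = grid["S_km2"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lj = np.where(s > 0, (a @ p) / np.where(s > 0, s, 1.0), np.nan)
    return pd.Series(lj, index=grid.index, name="L")


def cell_esv(grid: pd.DataFrame, coeffs: EsvCoefficients) -> pd.DataFrame:
    """Cell value ESV_j (CNY) and intensity V_esv,j (CNY/km²).

    Areas are km² in the grid table; C_i is CNY/ha, hence the x100.
    """
    codes = [int(c) for c in coeffs.per_class.index]
    a_ha = _areas_matrix(grid, codes) * 100.0
    c = coeffs.per_class.to_numpy(dtype=float)
    esv = a_ha @ c
    s = grid["S_km2"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(s > 0, esv / np.where(s > 0, s, 1.0), np.nan)
    return pd.DataFrame({"ESV": esv, "V_esv": v}, index=grid.index)


def add_valuation_columns(grid: pd.DataFrame, scheme: ClassScheme,
                          coeffs: EsvCoefficients) -> pd.DataFrame:
    """Return the grid with derived columns L, ESV (CNY), V_esv (CNY/km²)."""
    out = grid.copy()
    out.attrs = dict(grid.attrs)
    out["L"] = lu_degree(grid, scheme)
    val = cell_esv(grid, coeffs)
    out["ESV"] = val["ESV"]
    out["V_esv"] = val["V_esv"]
    return out


def summarize_by_class(grid: pd.DataFrame, scheme: ClassScheme,
                       coeffs: EsvCoefficients) -> pd.DataFrame:
    """Per-class area, value and percentage share (layout of a summary table).

    Returns a DataFrame indexed by class code with columns ``name``,
    ``area_km2``, ``esv_cny``, ``esv_cny_billion`` and ``share_pct``; shares
    are percentages of the grand total and sum to 100 (up to rounding when
    displayed). The grand total appears as a final row labelled code 0.
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    codes = scheme.codes
    a = _areas_matrix(grid, codes)
    area_by_class = a.sum(axis=0)
    c = coeffs.per_class.loc[codes].to_numpy(dtype=float)
    esv_by_class = area_by_class * 100.0 * c
    total = esv_by_class.sum()
    if total <= 0:
        share = np.zeros_like(esv_by_class)
    else:
        share = esv_by_class / total * 100.0
    out = pd.DataFrame({
        "name": scheme.table["name"].loc[codes].to_numpy(),
        "area_km2": area_by_class,
        "esv_cny": esv_by_class,
        "esv_cny_billion": esv_by_class / 1e9,
        "share_pct": share,
    }, index=pd.Index(codes, name="code"))
    out.loc[0] = ["total", area_by_class.sum(), total, total / 1e9,
                  100.0 if total > 0 else 0.0]
    return out
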