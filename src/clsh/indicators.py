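"""Derived indicators and the screened indicator cube.

The evaluation system is a pressure-state-response (PSR) hierarchy whose
state layer follows the vigor-organization-resilience (VOR) triad.  This
module computes the formula-based state/response indicators —

* cultivated-land productivity  P_i = mean NPP_i x cultivated area A_i,
* biological abundance          I_bio = A_bio x 0.11 x a_i / A_i
  (cultivated-land term of the HJ/T192 biological-abundance index,
  normalization coefficient A_bio = 511.2642131067),
* equivalent-factor ecosystem-service values scaled off the grain-production
  baseline E_j = (1/7) sum_i a_i P_i Q_i / A,

and assembles them with the disaggregated panel indicators into the
19-indicator cube used for weighting and the composite index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AssemblyError, ConfigurationError, DomainError

ABIO = 511.2642131067          # biological-abundance normalization coefficient
CULTIVATED_WEIGHT = 0.11       # HJ/T192 weight of the cultivated-land class
ESV_YEAR_FACTOR = 1.0 / 7.0    # one-seventh convention of the grain baseline


@dataclass(frozen=True)
class IndicatorMeta:
    code: str
    name: str
    layer: str        # "pressure" | "state" | "response"
    factor: str       # factor group within the layer
    direction: int    # +1 benefit, -1 cost
    weight: float | None  # published comprehensive weight; None = screened out

    @property
    def retained(self) -> bool:
        return self.weight is not None


_REGISTRY_ROWS = [
    # code  name                                   layer       factor                    dir  weight
    ("D1",  "population density",                  "pressure", "population growth",      -1, 0.0130),
    ("D2",  "urbanization rate",                   "pressure", "population growth",      -1, None),
    ("D3",  "GDP per capita",                      "pressure", "economic driving force", -1, None),
    ("D4",  "economic density",                    "pressure", "economic driving force", -1, 0.0302),
    ("D5",  "land reclamation rate",               "pressure", "land use intensity",     -1, 0.0338),
    ("D6",  "pesticide application intensity",     "pressure", "land use intensity",     -1, 0.0385),
    ("D7",  "fertilizer application intensity",    "pressure", "land use intensity",     -1, 0.0401),
    ("D8",  "agricultural plastic film amount",    "pressure", "land use intensity",     -1, None),
    ("D9",  "cultivated land productivity",        "state",    "vitality",               +1, 0.0520),
    ("D10", "NDVI",                                "state",    "vitality",               +1, 0.0336),
    ("D11", "landscape fragmentation index",       "state",    "ecological structure",   -1, None),
    ("D12", "biological abundance",                "state",    "ecological structure",   +1, 0.0335),
    ("D13", "agricultural output per capita",      "state",    "economic structure",     +1, None),
    ("D14", "agricultural output share",           "state",    "economic structure",     +1, 0.0753),
    ("D15", "agricultural employee share",         "state",    "social structure",       +1, 0.0396),
    ("D16", "rural population carrying capacity",  "state",    "social structure",       -1, None),
    ("D17", "per capita cultivated land area",     "state",    "restoring force",        +1, 0.0395),
    ("D18", "ecological elasticity",               "state",    "restoring force",        +1, None),
    ("D19", "grain per capita",                    "response", "socio-economic",         +1, 0.0389),
    ("D20", "farmer net income per capita",        "response", "socio-economic",         +1, 0.0286),
    ("D21", "agricultural mechanization level",    "response", "socio-economic",         +1, 0.0577),
    ("D22", "agricultural power intensity",        "response", "socio-economic",         +1, 0.0285),
    ("D23", "irrigation assurance rate",           "response", "socio-economic",         +1, None),
    ("D24", "climate regulation function",         "response", "environmental-ecological", +1, 0.1044),
    ("D25", "waste treatment function",            "response", "environmental-ecological", +1, 0.1044),
    ("D26", "soil conservation function",          "response", "environmental-ecological", +1, 0.1044),
    ("D27", "biodiversity maintenance function",   "response", "environmental-ecological", +1, 0.1044),
]

REGISTRY: dict[str, IndicatorMeta] = {
    r[0]: IndicatorMeta(code=r[0], name=r[1], layer=r[2], factor=r[3], direction=r[4], weight=r[5])
    for r in _REGISTRY_ROWS
}

RETAINED_CODES: list[str] = [m.code for m in REGISTRY.values() if m.retained]


def published_weights(renormalize: bool = True) -> pd.Series:
    """The published comprehensive weights of the 19 retained indicators."""
    w = pd.Series({c: REGISTRY[c].weight for c in RETAINED_CODES}, name="weight")
    return w / w.sum() if renormalize else w


# ---------------------------------------------------------------------------
# formula-based indicators
# ---------------------------------------------------------------------------


def cultivated_productivity(npp_mean, cultivated_area_hm2):
    """Total cultivated-land productivity P_i = mean NPP x cultivated area.

    Units: (gC/m^2/yr) x hm^2, kept as-is; the min-max normalization later
    removes the scale.
    """
    npp = np.asarray(npp_mean, dtype=float)
    area = np.asarray(cultivated_area_hm2, dtype=float)
    if (npp < 0).any() or (area < 0).any():
        raise DomainError("NPP and cultivated area must be nonnegative")
    return npp * area


def biological_abundance(cultivated_area_hm2, cell_area_hm2):
    """Cultivated-land biological-abundance index, in [0, 0.11 * A_bio]."""
    a = np.asarray(cultivated_area_hm2, dtype=float)
    big_a = np.asarray(cell_area_hm2, dtype=float)
    if (big_a <= 0).any():
        raise DomainError("cell area must be positive")
    if ((a < 0) | (a > big_a * (1 + 1e-12))).any():
        raise DomainError("cultivated area must lie in [0, cell area]")
    return ABIO * CULTIVATED_WEIGHT * a / big_a


def grain_economic_value(crop_table: pd.DataFrame, total_grain_area_hm2: float) -> float:
    """Grain-production baseline E_j (yuan/hm^2).

    E_j = (1/7) sum_i a_i P_i Q_i / A over crops i with area a_i (hm^2),
    price P_i (yuan/kg) and unit yield Q_i (kg/hm^2); A is the total grain
    area.  The 1/7 factor is the national equivalent-factor convention (one
    unit of standard equivalent is one-seventh of the grain market value).
    """
    if total_grain_area_hm2 <= 0:
        raise DomainError("total grain area must be positive")
    cols = ["area_hm2", "price_yuan_per_kg", "yield_kg_per_hm2"]
    vals = crop_table[cols].to_numpy(dtype=float)
    if (vals < 0).any():
        raise DomainError("crop areas, prices and yields must be nonnegative")
    total = float((vals[:, 0] * vals[:, 1] * vals[:, 2]).sum())
    return ESV_YEAR_FACTOR * total / total_grain_area_hm2


#: Base equivalent ratios of the nine farmland ecosystem services relative to
#: the grain-production baseline (grain = 1 by construction).  Derived
#: constants: each published coefficient divided by the published baseline.
ESV_BASE_RATIOS: dict[str, float] = {
    "grain_production": 1.00,
    "raw_material_production": 0.39,
    "gas_regulation": 0.72,
    "climate_regulation": 0.97,
    "hydrological_regulation": 0.77,
    "waste_disposal": 1.39,
    "soil_conservation": 1.47,
    "biodiversity_maintenance": 1.02,
    "aesthetic_landscape": 0.17,
}

#: Services used as the four environmental-ecological response indicators.
ESV_RESPONSE_SERVICES: dict[str, str] = {
    "D24": "climate_regulation",
    "D25": "waste_disposal",
    "D26": "soil_conservation",
    "D27": "biodiversity_maintenance",
}


def revise_esv_coefficients(
    ej_yuan_per_hm2: float, base_ratios: dict[str, float] | None = None
) -> pd.DataFrame:
    """Revised per-area service-value coefficients (yuan/hm^2/yr).

    Each service's coefficient is its base equivalent ratio times the local
    grain baseline E_j; the grain-production ratio must be 1.
    """
    ratios = ESV_BASE_RATIOS if base_ratios is None else base_ratios
    if "grain_production" not in ratios:
        raise ConfigurationError("grain_production ratio missing")
    if abs(ratios["grain_production"] - 1.0) > 1e-12:
        raise ConfigurationError("grain_production base ratio must equal 1")
    return pd.DataFrame(
        {
            "service": list(ratios),
            "base_ratio": list(ratios.values()),
            "coefficient_yuan_per_hm2": [r * ej_yuan_per_hm2 for r in ratios.values()],
        }
    )


def esv_response_indicators(
    esv_table: pd.DataFrame, cultivated_area: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell service values (yuan/yr) for the four response indicators.

    value = coefficient_s x cultivated_area_i for each service s in D24-D27.
    """
    coeff = esv_table.set_index("service")["coefficient_yuan_per_hm2"]
    missing = [s for s in ESV_RESPONSE_SERVICES.values() if s not in coeff.index]
    if missing:
        raise ConfigurationError(f"services missing from ESV table: {missing}")
    frames = []
    for code, service in ESV_RESPONSE_SERVICES.items():
        f = cultivated_area[["cell_id", "year"]].copy()
        f["indicator"] = code
        f["value"] = coeff[service] * cultivated_area["cultivated_area_hm2"].to_numpy()
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cube assembly
# ---------------------------------------------------------------------------


def assemble_indicator_cube(
    series: pd.DataFrame | list[pd.DataFrame],
    retained: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble grid value series into the screened indicator cube.

    Accepts one long table or a list of them (cell_id, year, indicator,
    value), restricts to the retained indicator set, attaches direction and
    layer metadata, and verifies completeness: every retained indicator must
    have a value for every (cell, year) present.
    """
    retained = RETAINED_CODES if retained is None else list(retained)
    cube = pd.concat(
        series if isinstance(series, list) else [series], ignore_index=True
    )
    unknown = set(retained) - set(REGISTRY)
    if unknown:
        raise AssemblyError(f"unknown indicator codes: {sorted(unknown)}")
    missing_series = set(retained) - set(cube["indicator"].unique())
    if missing_series:
        raise AssemblyError(f"missing indicator series: {sorted(missing_series)}")
    cube = cube[cube["indicator"].isin(retained)].copy()

    cells = cube["cell_id"].unique()
    years = cube["year"].unique()
    expected = len(cells) * len(years) * len(retained)
    counts = cube.groupby("indicator").size()
    if len(cube) != expected or cube.duplicated(["cell_id", "year", "indicator"]).any():
        bad = counts[counts != len(cells) * len(years)].index.tolist()
        raise AssemblyError(
            f"incomplete cube: expected {expected} rows, got {len(cube)}"
            + (f"; irregular indicators: {bad}" if bad else "")
        )
    if not np.isfinite(cube["value"]).all():
        raise AssemblyError("non-finite values in indicator cube")

    cube["direction"] = cube["indicator"].map(lambda c: REGISTRY[c].direction)
    cube["layer"] = cube["indicator"].map(lambda c: REGISTRY[c].layer)
    return cube.sort_values(["indicator", "year", "cell_id"]).reset_index(drop=True)
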