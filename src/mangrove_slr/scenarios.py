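"""Relative sea-level-rise scenario projections for coastal Haikou/Dongzhaigang.

Holds the per-RCP, per-year sea-level quantiles (cm above a 2000 baseline)
from the CMIP5-based projection table for the Haikou coast, and derives the
average-rate block, interpolated levels, and mangrove survival-threshold
flags from them.

Two epoch constants coexist deliberately. Levels are relative to the CMIP5
base year 2000 (``baseline_year``). The published average rates, however,
are reproduced exactly by dividing each level by the span from 2005
(``rate_origin_year``): e.g. 650 mm / 95 yr = 6.84 mm yr⁻¹ at 2100. Both
are configurable fields so the discrepancy stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpanError, OutOfRangeError

__all__ = [
    "QUANTILES", "ScenarioTable", "HistoricalContext", "builtin_scenario_table",
    "level_at", "rate_from_level", "rate_table", "threshold_flags",
    "SURVIVAL_THRESHOLDS_MM_PER_YR",
]

QUANTILES = ("p5", "p17", "mean", "p83", "p95")

#: GMSL-rise rates above which mangrove survival is threatened:
#: "likely" at >90% probability, "extremely likely" at >95%.
SURVIVAL_THRESHOLDS_MM_PER_YR = {"likely": 6.1, "extremely_likely": 7.6}

# Projected relative sea-level rise (cm above 2000) for the Haikou coast.
# Columns: scenario, year, then the 5/17/mean/83/95 quantiles.
_BUILTIN_LEVELS_CM = [
    # scenario, year,  p5, p17, mean, p83, p95
    ("RCP2.6", 2030,   8,  12,  18,  23,  27),
    ("RCP2.6", 2050,  14,  21,  31,  42,  49),
    ("RCP2.6", 2100,  26,  42,  65,  90, 111),
    ("RCP4.5", 2030,   8,  12,  18,  23,  27),
    ("RCP4.5", 2050,  16,  23,  33,  43,  51),
    ("RCP4.5", 2100,  34,  51,  75, 102, 123),
    ("RCP8.5", 2030,   8,  12,  18,  24,  28),
    ("RCP8.5", 2050,  19,  26,  36,  46,  54),
    ("RCP8.5", 2100,  52,  70,  96, 125, 151),
]


@dataclass
class ScenarioTable:
    """Per-scenario sea-level quantiles (cm) relative to ``baseline_year``.

    ``entries`` is a tidy DataFrame with columns scenario, year, quantile,
    level_cm. ``subsidence_rate`` (mm yr⁻¹, with 1-sigma uncertainty) is
    carried as metadata only: the levels are already *relative* sea level.
    """

    entries: pd.DataFrame
    baseline_year: int = 2000
    rate_origin_year: int = 2005
    subsidence_rate: tuple[float, float] | None = None

    def __post_init__(self):
        required = {"scenario", "year", "quantile", "level_cm"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"scenario table missing columns: {sorted(missing)}")
        wide = self.entries.pivot_table(index=["scenario", "year"],
                                        columns="quantile", values="level_cm")
        for lo, hi in zip(QUANTILES[:-1], QUANTILES[1:]):
            if lo in wide and hi in wide and not (wide[lo] <= wide[hi]).all():
                raise ValueError(f"quantile ordering violated: {lo} > {hi}")
        if (self.entries["level_cm"] < 0).any():
            raise ValueError("negative sea-level entries")

    @property
    def scenarios(self) -> list[str]:
        return sorted(self.entries["scenario"].unique())

    def years(self, scenario: str) -> np.ndarray:
        y = np.sort(self.entries.loc[self.entries["scenario"] == scenario,
                                     "year"].unique())
        return y

    def to_csv(self, path) -> None:
        wide = self.entries.pivot_table(index=["scenario", "year"],
                                        columns="quantile", values="level_cm")
        wide = wide.reindex(columns=list(QUANTILES)).reset_index()
        with open(path, "w") as fh:
            fh.write(f"# baseline_year={self.baseline_year} "
                     f"rate_origin_year={self.rate_origin_year}\n")
            wide.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScenarioTable":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
            wide = pd.read_csv(fh)
        entries = wide.melt(id_vars=["scenario", "year"],
                            var_name="quantile", value_name="level_cm")
        return cls(entries, baseline_year=int(meta["baseline_year"]),
                   rate_origin_year=int(meta["rate_origin_year"]))


@dataclass
class HistoricalContext:
    """Observed local relative SLR: 4.6 mm yr⁻¹ around Dongzhaigang, 1980–2018.

    ``delta_h_2000_2018`` (cm) is the observed rise over 2000–2018; the
    published record never prints it, so the default extrapolates the
    observed rate over the 18-year span: 0.46 cm yr⁻¹ × 18 = 8.28 cm.
    """

    observed_rslr_rate: float = 4.6   # mm per year, 1980-2018
    delta_h_2000_2018: float = field(default=4.6 * 18 / 10)  # cm

    def __post_init__(self):
        if self.delta_h_2000_2018 < 0:
            raise ValueError("delta_h_2000_2018 must be non-negative")


def builtin_scenario_table() -> ScenarioTable:
    """The built-in Haikou projection table (RCP 2.6/4.5/8.5 × 2030/2050/2100)."""
    rows = []
    for scenario, year, p5, p17, mean, p83, p95 in _BUILTIN_LEVELS_CM:
        for quantile, level in zip(QUANTILES, (p5, p17, mean, p83, p95)):
            rows.append((scenario, year, quantile, float(level)))
    entries = pd.DataFrame(rows, columns=["scenario", "year", "quantile",
                                          "level_cm"])
    return ScenarioTable(entries, baseline_year=2000, rate_origin_year=2005,
                         subsidence_rate=(1.09, 3.22))


def level_at(table: ScenarioTable, scenario: str, year: float,
             quantile: str = "mean") -> float:
    """Sea level (cm above baseline) at a year, linearly interpolated.

    Exact at tabulated years; linear between them; refuses extrapolation.
    """
    if quantile not in QUANTILES:
        raise ValueError(f"unknown quantile {quantile!r}; use one of {QUANTILES}")
    if scenario not in table.scenarios:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"table has {table.scenarios}")
    sel = table.entries[(table.entries["scenario"] == scenario)
                        & (table.entries["quantile"] == quantile)]
    sel = sel.sort_values("year")
    years = sel["year"].to_numpy(dtype=float)
    levels = sel["level_cm"].to_numpy(dtype=float)
    if not (years[0] <= year <= years[-1]):
        raise OutOfRangeError(
            f"year {year} outside tabulated range [{years[0]:g}, {years[-1]:g}]")
    return float(np.interp(year, years, levels))


def rate_from_level(level_cm: float, year: float, rate_origin_year: float) -> float:
    """Average rise rate (mm yr⁻¹) implied by a level reached at ``year``."""
    span = year - rate_origin_year
    if span <= 0:
        raise InvalidSpanError(f"year {year} must exceed origin {rate_origin_year}")
    return level_cm * 10.0 / span


def rate_table(table: ScenarioTable) -> pd.DataFrame:
    """Average-rate block (mm yr⁻¹) for every tabulated scenario/year/quantile."""
    out = table.entries.copy()
    out["rate_mm_per_yr"] = [
        rate_from_level(lv, yr, table.rate_origin_year)
        for lv, yr in zip(out["level_cm"], out["year"])
    ]
    return out


def threshold_flags(rates: pd.DataFrame,
                    thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Flag rates strictly exceeding each survival threshold.

    Adds one boolean column per threshold name (default: likely 6.1,
    extremely_likely 7.6 mm yr⁻¹).
    """
    if thresholds is None:
        thresholds = SURVIVAL_THRESHOLDS_MM_PER_YR
    if any(t <= 0 for t in thresholds.values()):
        raise ValueError("thresholds must be positive")
    out = rates.copy()
    for name, value in thresholds.items():
        out[f"exceeds_{name}"] = out["rate_mm_per_yr"] > value
    return out
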