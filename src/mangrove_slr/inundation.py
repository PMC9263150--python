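"""Bathtub inundation of mangrove habitat under projected sea-level rise.

The future mean sea level in the DEM datum is

    H = H0 − ΔH_2000–2018 + ΔH_2000–N − Va × T

where H0 is the elevation of the DEM contour nearest the mangrove's
seaward boundary (taken as current mean sea level), ΔH_2000–2018 the
observed rise since the scenario baseline, ΔH_2000–N the projected rise to
the target year N, Va the vertical sediment accretion rate (assumed
constant), and T the accretion span in years. A mangrove cell is lost when
its elevation falls strictly below H — equivalently, when its accreted
surface (elevation + Va·T) falls below the no-accretion water level — so a
wetland accreting faster than the sea rises never drowns.

Va is mapped over space by nearest-station (Voronoi) assignment of the
per-core rates, since a handful of dated cores must represent the whole
forest. The default model is a pure bathtub (every cell below H counts);
a sea-connected variant restricts losses to cells hydrologically
8-connected to the sea through sub-H terrain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString
from skimage import measure

from .errors import NoContourError, OutOfRangeError
from .raster import Raster, require_aligned
from .scenarios import (QUANTILES, ScenarioTable, level_at, rate_from_level,
                        SURVIVAL_THRESHOLDS_MM_PER_YR)

__all__ = [
    "SeaLevelContext", "AccretionField", "InundationResult",
    "select_h0_contour", "future_sea_level", "build_accretion_field",
    "inundation_mask", "loss_summary", "scenario_matrix", "results_table",
]

logger = logging.getLogger(__name__)


@dataclass
class SeaLevelContext:
    """Vertical bookkeeping for the sea-level equation (all metres/years)."""

    h0: float                          # current MSL height in DEM datum, m
    delta_h_2000_2018: float = 8.28    # cm, observed rise over 2000-2018
    contour_interval: float = 0.1      # m
    accretion_reference_year: int = 2018

    def __post_init__(self):
        if self.contour_interval <= 0:
            raise ValueError("contour_interval must be positive")


@dataclass
class AccretionField:
    """Per-cell vertical accretion rates (cm yr⁻¹) over the mangrove mask."""

    va: Raster                          # cm per year; NaN outside the mask
    stations: list[str]
    assignment: Raster                  # station index per cell; -1 outside

    def __post_init__(self):
        inside = ~np.isnan(self.va.data)
        if (self.va.data[inside] < 0).any():
            raise ValueError("negative accretion rate inside the mask")


@dataclass
class InundationResult:
    """Loss accounting for one scenario/year across sea-level quantiles."""

    scenario: str
    year: int
    h_future_m: dict[str, float]
    lost_area_hm2: dict[str, float]
    lost_pct: dict[str, float]
    total_area_hm2: float
    flags: dict[str, bool] = field(default_factory=dict)


def _seaward_boundary_cells(dem: Raster, mask: np.ndarray) -> np.ndarray:
    """Mask cells 4-adjacent to a lower-lying non-mask cell (the outer,
    seaward boundary; the landward boundary abuts higher ground)."""
    z = dem.data
    rows, cols = mask.shape
    out = np.zeros_like(mask)
    shifts = ((1, 0), (-1, 0), (0, 1), (0, -1))
    for dr, dc in shifts:
        nb_mask = np.zeros_like(mask)
        nb_z = np.full_like(z, np.inf, dtype=float)
        rs = slice(max(dr, 0), rows + min(dr, 0))
        rd = slice(max(-dr, 0), rows + min(-dr, 0))
        cs = slice(max(dc, 0), cols + min(dc, 0))
        cd = slice(max(-dc, 0), cols + min(-dc, 0))
        nb_mask[rd, cd] = mask[rs, cs]
        nb_z[rd, cd] = z[rs, cs]
        out |= mask & ~nb_mask & (nb_z < z)
    return out


def select_h0_contour(dem: Raster, mangrove_mask: Raster,
                      contour_interval: float = 0.1
                      ) -> tuple[float, list[LineString]]:
    """Pick the elevation contour nearest the mangrove's seaward boundary.

    Candidate contours are drawn at every multiple of ``contour_interval``
    within the DEM's range; the winning level minimizes the mean distance
    from the seaward boundary cells of the mask to the contour, and is
    returned with its georeferenced polylines as the current mean sea
    level H0.
    """
    require_aligned(dem, mangrove_mask)
    mask = mangrove_mask.data.astype(bool)
    if not mask.any():
        raise NoContourError("mangrove mask is empty")
    z = dem.data[dem.valid_mask()]
    lo, hi = float(z.min()), float(z.max())
    levels = np.arange(np.ceil(lo / contour_interval),
                       np.floor(hi / contour_interval) + 1) * contour_interval
    boundary = np.argwhere(_seaward_boundary_cells(dem, mask))
    if len(boundary) == 0:
        boundary = np.argwhere(mask)
    bx, by = dem.transform.cell_center(boundary[:, 0], boundary[:, 1])
    bpts = np.column_stack([bx, by])

    best = None
    for level in levels:
        contours = measure.find_contours(dem.data, level)
        if not contours:
            continue
        verts = np.vstack(contours)
        vx, vy = dem.transform.cell_center(verts[:, 0], verts[:, 1])
        tree = cKDTree(np.column_stack([vx, vy]))
        dist, _ = tree.query(bpts)
        score = float(dist.mean())
        if best is None or score < best[0]:
            best = (score, float(level), contours)
    if best is None:
        raise NoContourError("no contour level crosses the DEM "
                             "(flat or single-valued elevation)")
    score, h0, contours = best
    if score > 3 * dem.cell_size:
        logger.warning("nearest contour (%.3f m) is %.1f m from the mask "
                       "boundary; contour interval may be coarser than the "
                       "mask relief", h0, score)
    polylines = []
    for arr in contours:
        x, y = dem.transform.cell_center(arr[:, 0], arr[:, 1])
        if len(x) >= 2:
            polylines.append(LineString(np.column_stack([x, y])))
    return h0, polylines


def future_sea_level(ctx: SeaLevelContext, table: ScenarioTable, scenario: str,
                     year: int, quantile: str = "mean", va=0.0):
    """Eq.-of-state for the future water level H (metres in the DEM datum).

    ``va`` is a vertical accretion rate in cm yr⁻¹ — a scalar, or an array
    for spatially varying accretion (returns an array then). Accretion
    accrues over T = year − accretion_reference_year.
    """
    t_span = year - ctx.accretion_reference_year
    if t_span < 0:
        raise OutOfRangeError(
            f"target year {year} precedes accretion reference "
            f"{ctx.accretion_reference_year}")
    level_cm = level_at(table, scenario, year, quantile)
    va = np.asarray(va, dtype=float)
    h = (ctx.h0 - ctx.delta_h_2000_2018 / 100.0 + level_cm / 100.0
         - va / 100.0 * t_span)
    return h if h.ndim else float(h)


def build_accretion_field(core_rates: dict[str, float],
                          core_sites: list[tuple[str, int, int]],
                          mask: Raster) -> AccretionField:
    """Nearest-station (Voronoi, grid coordinates) Va assignment over the mask."""
    if not core_sites:
        raise ValueError("need at least one core site")
    stations = [s for s, _, _ in core_sites]
    missing = [s for s in stations if s not in core_rates]
    if missing:
        raise ValueError(f"no rate for stations {missing}")
    sites = np.array([(r, c) for _, r, c in core_sites], dtype=float)
    tree = cKDTree(sites)
    cells = np.argwhere(mask.data.astype(bool))
    _, idx = tree.query(cells.astype(float))
    va = np.full(mask.shape, np.nan)
    label = np.full(mask.shape, -1, dtype=np.int32)
    rates = np.array([core_rates[s] for s in stations])
    va[cells[:, 0], cells[:, 1]] = rates[idx]
    label[cells[:, 0], cells[:, 1]] = idx
    return AccretionField(va=mask.like(va), stations=stations,
                          assignment=mask.like(label))


def inundation_mask(dem: Raster, mangrove_mask: Raster, h_future,
                    connectivity: str = "off") -> Raster:
    """Cells lost to inundation: mangrove and elevation strictly below H.

    ``h_future`` may be a scalar or a per-cell array (metres). With
    ``connectivity='sea-connected'`` a lost cell must additionally be
    8-connected to the seaward (northern) raster edge through sub-H cells.
    """
    require_aligned(dem, mangrove_mask)
    h = np.asarray(h_future, dtype=float)
    below = dem.data < h
    lost = mangrove_mask.data.astype(bool) & below & dem.valid_mask()
    if connectivity == "sea-connected":
        from scipy import ndimage
        labels, n = ndimage.label(below, structure=np.ones((3, 3), dtype=bool))
        keep = np.unique(labels[0, :])
        keep = keep[keep > 0]
        lost &= np.isin(labels, keep)
    elif connectivity != "off":
        raise ValueError("connectivity must be 'off' or 'sea-connected'")
    return dem.like(lost)


def loss_summary(lost_mask: Raster, mangrove_mask: Raster,
                 cell_size: float | None = None
                 ) -> tuple[float, float, float]:
    """(lost_area_hm2, lost_pct, total_area_hm2) by cell accounting.

    1 hm² = 10⁴ m²; area = cell count × cell_size².
    """
    require_aligned(lost_mask, mangrove_mask)
    if cell_size is None:
        cell_size = lost_mask.cell_size
    cell_hm2 = cell_size ** 2 / 1e4
    lost = float(np.count_nonzero(lost_mask.data) * cell_hm2)
    total = float(np.count_nonzero(mangrove_mask.data) * cell_hm2)
    pct = 100.0 * lost / total if total > 0 else 0.0
    return lost, pct, total


def scenario_matrix(ctx: SeaLevelContext, table: ScenarioTable,
                    accretion_field: AccretionField, dem: Raster,
                    mangrove_mask: Raster, scenarios=None, years=None,
                    quantiles=None, connectivity: str = "off"
                    ) -> list[InundationResult]:
    """Evaluate the loss cross-product scenario × year × quantile.

    Per-cell Va enters the water-level comparison cellwise; the reported
    ``h_future_m`` uses the mask-mean Va as a representative scalar. The
    survival-threshold flags compare the mean-level rise rate with the
    6.1 / 7.6 mm yr⁻¹ thresholds.
    """
    if scenarios is None:
        scenarios = table.scenarios
    if quantiles is None:
        quantiles = list(QUANTILES)
    mask = mangrove_mask.data.astype(bool)
    va = np.where(mask, np.nan_to_num(accretion_field.va.data, nan=0.0), 0.0)
    va_mean = float(va[mask].mean()) if mask.any() else 0.0
    results = []
    for scenario in scenarios:
        year_list = years if years is not None else table.years(scenario)
        for year in year_list:
            h_rep, lost_area, lost_pct = {}, {}, {}
            total = None
            for q in quantiles:
                h_cell = future_sea_level(ctx, table, scenario, int(year),
                                          q, va=va)
                lost = inundation_mask(dem, mangrove_mask, h_cell,
                                       connectivity=connectivity)
                la, lp, total = loss_summary(lost, mangrove_mask)
                lost_area[q], lost_pct[q] = la, lp
                h_rep[q] = future_sea_level(ctx, table, scenario, int(year),
                                            q, va=va_mean)
            rate = rate_from_level(level_at(table, scenario, int(year), "mean"),
                                   int(year), table.rate_origin_year)
            flags = {f"exceeds_{name}": rate > thr
                     for name, thr in SURVIVAL_THRESHOLDS_MM_PER_YR.items()}
            results.append(InundationResult(
                scenario=scenario, year=int(year), h_future_m=h_rep,
                lost_area_hm2=lost_area, lost_pct=lost_pct,
                total_area_hm2=total, flags=flags))
    return results


def results_table(results: list[InundationResult]) -> pd.DataFrame:
    """Tidy loss table: one row per scenario/year/quantile."""
    rows = []
    for res in results:
        for q in res.h_future_m:
            rows.append({
                "scenario": res.scenario, "year": res.year, "quantile": q,
                "h_future_m": res.h_future_m[q],
                "lost_area_hm2": res.lost_area_hm2[q],
                "lost_pct": res.lost_pct[q],
                "total_area_hm2": res.total_area_hm2,
                **res.flags,
            })
    return pd.DataFrame(rows)
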