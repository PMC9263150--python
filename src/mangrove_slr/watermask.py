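"""Water masks, shorelines, and edge migration from multiband reflectance.

Open water is detected with a multi-band spectral relationship: a pixel is
water when green + red − NIR − SWIR1 exceeds a threshold T (strict
inequality; 500 on the 0–10000 surface-reflectance scale). Isolated inland
water bodies (aquaculture ponds, lakes) are then removed by keeping only
the water components 8-connected to the sea, replacing the manual
visual-interpretation step with a deterministic connectivity rule. The
shoreline is the set of shared edges between 4-adjacent water and land
cells, merged into georeferenced polylines, so its total length equals the
water/land edge-pair count times the cell size exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, MultiLineString, mapping
from shapely.ops import linemerge

from .errors import AlignmentError
from .raster import GridTransform, Raster
from .synthetic_site import MultibandImage

__all__ = [
    "DEFAULT_THRESHOLD", "WaterMaskResult", "spectral_water_index",
    "threshold_mask", "remove_inland_water", "extract_shoreline",
    "extract_water_mask", "edge_migration", "shoreline_to_geojson",
]

#: Segmentation threshold T on the integer water index.
DEFAULT_THRESHOLD = 500

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class WaterMaskResult:
    raw_mask: Raster
    filtered_mask: Raster
    removed_components: int
    shoreline: list[LineString]
    shoreline_length_m: float
    threshold_used: int


def spectral_water_index(image: MultibandImage) -> np.ndarray:
    """Per-pixel water index green + red − NIR − SWIR1 (integer).

    Nodata in any band propagates to the index as the image's nodata value.
    """
    g = image.green.astype(np.int64)
    r = image.red.astype(np.int64)
    n = image.nir.astype(np.int64)
    s = image.swir1.astype(np.int64)
    index = g + r - n - s
    if image.nodata is not None:
        bad = ((image.green == image.nodata) | (image.red == image.nodata)
               | (image.nir == image.nodata) | (image.swir1 == image.nodata))
        index[bad] = image.nodata
    return index


def threshold_mask(index: np.ndarray, t: int = DEFAULT_THRESHOLD,
                   nodata: int | None = None) -> np.ndarray:
    """Boolean water mask: index strictly greater than t; nodata is land."""
    mask = index > t
    if nodata is not None:
        mask &= index != nodata
    return mask


def remove_inland_water(mask: np.ndarray,
                        sea_seed: tuple[int, int] | str = "boundary"
                        ) -> tuple[np.ndarray, int]:
    """Keep only water 8-connected to the sea; count removed components.

    ``sea_seed`` is either a (row, col) cell inside the sea, or
    ``"boundary"`` (default), which keeps every component touching the
    seaward (northern, row 0) edge of the raster. Returns (filtered mask,
    number of removed components); an empty result means no water reaches
    the seed.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(mask), 0
    if sea_seed == "boundary":
        keep = np.unique(labels[0, :])
    else:
        r, c = sea_seed
        keep = np.array([labels[r, c]])
    keep = keep[keep > 0]
    filtered = np.isin(labels, keep)
    removed = n - len(np.unique(keep))
    return filtered, int(removed)


def _boundary_segments(mask: np.ndarray) -> list[tuple]:
    """Shared cell edges between 4-adjacent water/land pairs, as segments
    in fractional (row, col) node coordinates on the cell-corner lattice."""
    segments = []
    water = np.asarray(mask, dtype=bool)
    rows, cols = water.shape
    # vertical neighbours (r, c)-(r+1, c): horizontal edge at row r+1
    diff = water[:-1, :] != water[1:, :]
    for r, c in np.argwhere(diff):
        segments.append(((r + 1, c), (r + 1, c + 1)))
    # horizontal neighbours (r, c)-(r, c+1): vertical edge at col c+1
    diff = water[:, :-1] != water[:, 1:]
    for r, c in np.argwhere(diff):
        segments.append(((r, c + 1), (r + 1, c + 1)))
    return segments


def extract_shoreline(mask: np.ndarray, transform: GridTransform
                      ) -> tuple[list[LineString], float]:
    """Trace water/land cell boundaries as georeferenced polylines.

    Only internal water/land adjacencies contribute; the raster border is
    not a shoreline. Total length = (number of 4-adjacent water/land
    pairs) × cell_size for square cells.
    """
    segs = _boundary_segments(mask)
    if not segs:
        return [], 0.0
    lines = []
    for (r0, c0), (r1, c1) in segs:
        x0, y0 = transform.node(r0, c0)
        x1, y1 = transform.node(r1, c1)
        lines.append(LineString([(x0, y0), (x1, y1)]))
    merged = linemerge(MultiLineString(lines))
    if isinstance(merged, LineString):
        polylines = [merged]
    else:
        polylines = list(merged.geoms)
    total = float(sum(line.length for line in polylines))
    return polylines, total


def extract_water_mask(image: MultibandImage, t: int = DEFAULT_THRESHOLD,
                       sea_seed="boundary") -> WaterMaskResult:
    """Full chain: index → threshold → inland-water removal → shoreline."""
    index = spectral_water_index(image)
    raw = threshold_mask(index, t, nodata=image.nodata)
    filtered, removed = remove_inland_water(raw, sea_seed=sea_seed)
    polylines, length = extract_shoreline(filtered, image.transform)
    base = Raster(raw, image.transform, image.crs)
    return WaterMaskResult(raw_mask=base, filtered_mask=base.like(filtered),
                           removed_components=removed, shoreline=polylines,
                           shoreline_length_m=length, threshold_used=t)


def _as_multiline(lines) -> MultiLineString:
    if isinstance(lines, LineString):
        return MultiLineString([lines])
    if isinstance(lines, MultiLineString):
        return lines
    return MultiLineString(list(lines))


def edge_migration(edge_old, edge_new, seaward_direction: tuple[float, float],
                   transect_spacing: float = 60.0,
                   stable_tolerance: float = 15.0,
                   max_search: float = 5000.0):
    """Signed shoreline displacement along transects normal to the old edge.

    At points spaced ``transect_spacing`` metres along the old edge, a
    transect is cast along the landward direction (the negated unit
    ``seaward_direction``); the displacement to the nearest intersection
    with the new edge is positive landward (retreat) and negative seaward
    (advance). Class is ``stable`` within ±``stable_tolerance`` metres
    (half a 30 m cell by default); transects that miss the new edge get
    NaN displacement and class ``missing``.

    Returns a list of dicts with keys transect_id, x, y, displacement_m,
    class.
    """
    old = _as_multiline(edge_old)
    new = _as_multiline(edge_new)
    if old.is_empty or new.is_empty:
        raise ValueError("both edges must be non-empty")
    sx, sy = seaward_direction
    norm = float(np.hypot(sx, sy))
    if norm == 0:
        raise ValueError("seaward_direction must be a non-zero vector")
    lx, ly = -sx / norm, -sy / norm      # landward unit vector

    records = []
    tid = 0
    for line in old.geoms:
        n_pts = max(int(line.length // transect_spacing) + 1, 2)
        for i in range(n_pts):
            pt = line.interpolate(min(i * transect_spacing, line.length))
            transect = LineString([
                (pt.x - lx * max_search, pt.y - ly * max_search),
                (pt.x + lx * max_search, pt.y + ly * max_search),
            ])
            inter = transect.intersection(new)
            if inter.is_empty:
                disp = float("nan")
                cls = "missing"
            else:
                pts = _flatten_points(inter)
                # signed landward projection of the nearest crossing
                disps = [(p[0] - pt.x) * lx + (p[1] - pt.y) * ly for p in pts]
                disp = min(disps, key=abs)
                if abs(disp) <= stable_tolerance:
                    cls = "stable"
                else:
                    cls = "landward" if disp > 0 else "seaward"
            records.append({"transect_id": tid, "x": pt.x, "y": pt.y,
                            "displacement_m": disp, "class": cls})
            tid += 1
    return records


def _flatten_points(geom) -> list[tuple[float, float]]:
    if geom.is_empty:
        return []
    if geom.geom_type == "Point":
        return [(geom.x, geom.y)]
    if geom.geom_type in ("LineString", "LinearRing"):
        return list(geom.coords)
    return [p for g in geom.geoms for p in _flatten_points(g)]


def shoreline_to_geojson(polylines, path, properties: dict | None = None) -> None:
    """Write polylines as a GeoJSON FeatureCollection of LineStrings."""
    features = [{
        "type": "Feature",
        "geometry": mapping(line),
        "properties": dict(properties or {}, segment=i),
    } for i, line in enumerate(polylines)]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def require_mask_alignment(mask: Raster, other: Raster) -> None:
    if not mask.aligned_with(other):
        raise AlignmentError("mask misaligned with companion raster")
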