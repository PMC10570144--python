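"""Apical-surface morphometry: polygon areas, cap/cortex measurement
regions, per-embryo intensity normalization and area-intensity regression.

The measurement geometry mirrors how apical myosin is quantified from
en-face images of a pseudostratified neuroepithelium: the inner border of
the bright junctional actomyosin rim bounds an "apical cap" region, and
the cap outline expanded outward by a fixed width (default 0.5 um) defines
the junctional "cortex" band. Intensities are normalized per embryo to
that embryo's mean staining intensity (set to 100%) to remove
inter-individual staining differences before groups are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.validation import explain_validity

from .stats import CorrelationResult, pearson

MITOTIC_GROUPS = frozenset({"pHH3+", "M"})


def _as_polygon(vertices: Sequence[Sequence[float]], cell_id: str | None = None) -> Polygon:
    pts = np.asarray(vertices, dtype=float)
    ident = f" (cell {cell_id})" if cell_id else ""
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError(f"polygon needs >= 3 (x, y) vertices{ident}")
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError(
            f"polygon is not simple{ident}: {explain_validity(poly)}")
    if poly.area == 0:
        raise ValueError(f"degenerate zero-area polygon{ident}")
    return poly


def polygon_area(vertices: Sequence[Sequence[float]], cell_id: str | None = None) -> float:
    """Absolute shoelace area (um^2) of a simple polygon.

    Invariant to vertex rotation, orientation reversal and rigid motion.
    Raises ValueError naming the cell for <3 vertices or self-intersection.
    """
    return _as_polygon(vertices, cell_id).area


def build_cap_and_cortex(
    vertices: Sequence[Sequence[float]],
    band_width: float = 0.5,
    *,
    join: str = "round",
    quad_segs: int = 64,
    cell_id: str | None = None,
) -> tuple[Polygon, Polygon]:
    """Cap region (polygon interior) and cortex band (outward offset ring).

    The band is the Minkowski offset of the polygon by ``band_width`` minus
    the polygon itself; round joins by default (``quad_segs`` arc segments
    per quarter circle), mitre available via ``join='mitre'``. With
    ``band_width == 0`` the band is empty and the cap equals the polygon.
    """
    if band_width < 0:
        raise ValueError("band_width must be >= 0")
    cap = _as_polygon(vertices, cell_id)
    if band_width == 0:
        return cap, Polygon()
    grown = cap.buffer(band_width, quad_segs=quad_segs, join_style=join)
    if grown.is_empty or not grown.is_valid:
        raise ValueError(f"offset failed on degenerate geometry (cell {cell_id})")
    band = grown.difference(cap)
    return cap, band


@dataclass
class RegionIntensity:
    mean: float
    n_pixels: int


def region_mean_intensity(
    raster: np.ndarray,
    region: Polygon,
    pixel_size: float,
) -> RegionIntensity:
    """Mean raster value over pixels whose centers fall inside ``region``.

    The raster is row-major with y increasing downward; pixel (r, c) has
    its center at ((c + 0.5) * pixel_size, (r + 0.5) * pixel_size) in um.
    Raises if the region covers no pixel center (too small for the
    resolution).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    from shapely import contains_xy

    minx, miny, maxx, maxy = region.bounds
    c0 = max(int(np.floor(minx / pixel_size - 0.5)), 0)
    r0 = max(int(np.floor(miny / pixel_size - 0.5)), 0)
    c1 = min(int(np.ceil(maxx / pixel_size + 0.5)), raster.shape[1] - 1)
    r1 = min(int(np.ceil(maxy / pixel_size + 0.5)), raster.shape[0] - 1)
    if c1 < c0 or r1 < r0:
        raise ValueError("region does not overlap the raster")
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    xs = (cc + 0.5) * pixel_size
    ys = (rr + 0.5) * pixel_size
    inside = contains_xy(region, xs.ravel(), ys.ravel()).reshape(xs.shape)
    n = int(inside.sum())
    if n == 0:
        raise ValueError("no pixel centers inside region (region too small "
                         "for this pixel size)")
    return RegionIntensity(mean=float(raster[r0:r1 + 1, c0:c1 + 1][inside].mean()),
                           n_pixels=n)


def measure_cells(
    cells: pd.DataFrame,
    intensity: np.ndarray,
    pixel_size: float,
    *,
    band_width: float = 0.5,
    quad_segs: int = 64,
) -> pd.DataFrame:
    """Measure cap and cortex mean intensities for every cell polygon.

    ``cells`` needs ``cell_id`` and ``vertices`` (sequence of (x, y) um, or
    a JSON string of one). Cells whose offset band leaves the raster are
    flagged ``on_border`` and their intensities set to NaN (they are
    excluded from normalization and regression downstream).
    """
    import json

    h, w = intensity.shape
    out = cells.copy()
    caps, cortices, areas, border = [], [], [], []
    for _, row in out.iterrows():
        verts = row["vertices"]
        if isinstance(verts, str):
            verts = json.loads(verts)
        cap, band = build_cap_and_cortex(verts, band_width,
                                         quad_segs=quad_segs,
                                         cell_id=str(row["cell_id"]))
        areas.append(cap.area)
        minx, miny, maxx, maxy = (cap if band.is_empty else band.union(cap)).bounds
        on_border = minx < 0 or miny < 0 or maxx > w * pixel_size or maxy > h * pixel_size
        border.append(on_border)
        if on_border:
            caps.append(np.nan)
            cortices.append(np.nan)
            continue
        caps.append(region_mean_intensity(intensity, cap, pixel_size).mean)
        cortices.append(
            region_mean_intensity(intensity, band, pixel_size).mean
            if not band.is_empty else np.nan)
    out["area_um2"] = areas
    out["cap_AU"] = caps
    out["cortex_AU"] = cortices
    out["on_border"] = border
    return out


def normalize_per_embryo(
    records: pd.DataFrame,
    *,
    compartments: tuple[str, ...] = ("cap_AU", "cortex_AU"),
) -> pd.DataFrame:
    """Express intensities as % of each embryo's mean staining intensity.

    For each embryo and each compartment independently,
    normalized = 100 * raw / mean(raw over that embryo's analysed cells,
    all groups pooled), so the within-embryo mean of normalized values is
    exactly 100. Adds ``cap_pct`` / ``cortex_pct`` columns. NaN intensities
    (border-flagged cells) are ignored in the mean and stay NaN.
    """
    if "embryo_id" not in records.columns:
        raise ValueError("records must carry embryo_id")
    out = records.copy()
    for comp in compartments:
        if comp not in out.columns:
            raise ValueError(f"missing intensity column {comp!r}")
        means = out.groupby("embryo_id")[comp].transform("mean")
        if (means == 0).any():
            bad = out.loc[means == 0, "embryo_id"].unique()
            raise ValueError(f"embryo mean intensity is zero for {list(bad)}")
        out[comp.replace("_AU", "_pct")] = 100.0 * out[comp] / means
    return out


def area_intensity_regression(
    records: pd.DataFrame,
    group: str,
    compartment: str = "cap_pct",
    *,
    area_col: str = "area_um2",
) -> CorrelationResult:
    """OLS line + Pearson r between apical area and normalized intensity
    within one group (e.g. pHH3+ cap), two-sided p from the t distribution
    with n-2 df."""
    sub = records[records["group"] == group]
    sub = sub[np.isfinite(sub[area_col]) & np.isfinite(sub[compartment])]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 finite records in group {group!r}")
    return pearson(sub[area_col], sub[compartment],
                   group=f"{group}/{compartment}")
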