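"""Seeded synthetic-data generator for every input modality of the
pipeline, with exported ground truth.

The generator emulates the measured structure of a pseudostratified
neuroepithelium imaged en face:

* apical mosaics — a Voronoi tessellation whose per-group mean apical
  areas follow the cell-cycle pattern of the tissue geometry ("flat":
  G2 cells dilated, mitotic cells constricted; "convex": mitotic cells
  retain large apices), with junctional (cortex) and apicomedial (cap)
  myosin intensities that fall with apical area in mitotic cells only,
  and per-embryo multiplicative staining scale factors;
* live traces — pulsatile apical-area series in which mitotic cells
  superimpose a constriction event reaching its minimum exactly at the
  annotated anaphase frame before re-dilating;
* apical surface profiles — noisy circular arcs of known radius;
* Ki-67 nuclei — 3D stacks with the stage-typical focus pattern and
  stage-scaled nuclear volume.

Identical (params, seed) yields bit-identical output; every generated
object has exactly one ground-truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .curvature import SurfaceProfile
from .morphometry import MITOTIC_GROUPS
from .pulses import CellTrace

# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """True generating parameters, one record per generated object."""

    kind: str
    table: pd.DataFrame
    params: dict
    seed: int

    def to_json(self, path) -> None:
        import json
        payload = {"kind": self.kind, "seed": int(self.seed),
                   "params": _jsonable(self.params),
                   "records": self.table.to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(_jsonable(payload), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# apical mosaics

#: default group mean apical areas (um^2) by geometry preset. On flat
#: geometry G2 cells are dilated while mitotic (and G1/S) apices are
#: small; on convex geometry M-phase cells retain large apices.
FLAT_GROUP_MEANS = {"G1/S": 25.0, "G2": 45.0, "M": 25.0}
CONVEX_GROUP_MEANS = {"G1/S": 25.0, "G2": 45.0, "M": 40.0}
#: mitotic-marker preset with the mouse posterior-neuropore group means
PHH3_GROUP_MEANS = {"pHH3-": 34.5, "pHH3+": 20.5}


@dataclass
class MosaicParams:
    """Parameters of the synthetic apical mosaic.

    The field is rescaled so that its total area equals the sum of target
    cell areas (cell count and group means are honored; ``field_width``
    fixes the aspect). ``group_sigma`` is the lognormal sigma of the
    per-cell area distribution used by the table-only sampler.
    """

    field_width: float = 100.0          # um
    pixel_size: float = 0.2             # um/px
    n_cells: int = 300
    geometry: str = "flat"              # "flat" | "convex"
    group_means: dict = field(default_factory=lambda: dict(FLAT_GROUP_MEANS))
    group_props: dict = field(
        default_factory=lambda: {"G1/S": 0.60, "G2": 0.25, "M": 0.15})
    group_sigma: float = 0.35           # lognormal sigma of log-area
    n_embryos: int = 1
    embryo_scales: tuple | None = None  # drawn lognormal(sd=0.25) if None
    alpha: float = 150.0                # AU, mitotic intensity intercept
    beta: float = -3.0                  # AU/um^2, mitotic slope (<= 0)
    interphase_mean: float = 100.0      # AU
    noise_sd: float = 10.0              # AU
    noise_rho: float = 0.7              # cap-cortex noise correlation
    rim_width: float = 0.5              # um, rendered cortical rim

    def __post_init__(self) -> None:
        props = np.array(list(self.group_props.values()), dtype=float)
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("group proportions must sum to 1")
        if any(m <= 0 for m in self.group_means.values()):
            raise ValueError("group mean areas must be > 0")
        if self.beta > 0:
            raise ValueError("mitotic intensity-area slope beta must be <= 0")
        if self.embryo_scales is not None:
            if len(self.embryo_scales) != self.n_embryos:
                raise ValueError("one scale factor per embryo required")
            if any(s <= 0 for s in self.embryo_scales):
                raise ValueError("embryo scale factors must be > 0")
        if set(self.group_means) != set(self.group_props):
            raise ValueError("group_means and group_props must share keys")
        gm = self.group_means
        if self.geometry == "flat" and {"G1/S", "G2", "M"} <= set(gm):
            if not (gm["G2"] > gm["G1/S"] and gm["G2"] > gm["M"]):
                raise ValueError("flat geometry requires G2 > G1/S ~ M")
        elif self.geometry == "convex" and {"G1/S", "G2", "M"} <= set(gm):
            if not (gm["G2"] >= gm["M"] > gm["G1/S"]):
                raise ValueError("convex geometry requires G2 >= M > G1/S")


def convex_mosaic_params(**kw) -> MosaicParams:
    kw.setdefault("geometry", "convex")
    kw.setdefault("group_means", dict(CONVEX_GROUP_MEANS))
    return MosaicParams(**kw)


def phh3_mosaic_params(**kw) -> MosaicParams:
    kw.setdefault("group_means", dict(PHH3_GROUP_MEANS))
    kw.setdefault("group_props", {"pHH3-": 0.8, "pHH3+": 0.2})
    return MosaicParams(**kw)


def noise_sd_for_r2(beta: float, area_sd: float, r2: float) -> float:
    """Intensity noise sd giving a target true R^2 for the linear
    intensity-area relation: R^2 = b^2 s_a^2 / (b^2 s_a^2 + s_e^2)."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    return abs(beta) * area_sd * np.sqrt((1 - r2) / r2)


def lognormal_area_sd(mean: float, sigma: float) -> float:
    """Sd of a lognormal with the given mean and log-sd sigma."""
    return mean * np.sqrt(np.exp(sigma**2) - 1)


def calibrated_regression_table(
    n: int,
    *,
    mean_area: float = 20.5,
    sigma: float = 0.35,
    alpha: float = 150.0,
    beta: float = -3.0,
    r2: float = 0.5,
    rho: float = 0.7,
    group: str = "pHH3+",
    seed: int = 0,
) -> pd.DataFrame:
    """Mitotic-style cell table whose intensity noise is calibrated to the
    realized area dispersion, so each dataset's true R^2 equals ``r2``
    exactly (parameter-recovery harness for the area-intensity
    regression)."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    areas = np.exp(rng.normal(np.log(mean_area) - sigma**2 / 2, sigma, n))
    sd_noise = abs(beta) * areas.std(ddof=1) * np.sqrt((1 - r2) / r2)
    cov = sd_noise**2 * np.array([[1, rho], [rho, 1]])
    eps = rng.multivariate_normal([0, 0], cov, size=n)
    return pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(n)],
        "embryo_id": "e0", "group": group, "area_um2": areas,
        "cap_AU": alpha + beta * areas + eps[:, 0],
        "cortex_AU": alpha + beta * areas + eps[:, 1]})


def _draw_intensities(rng, areas, groups, embryos, scales, p: MosaicParams):
    mitotic = np.isin(groups, list(MITOTIC_GROUPS))
    mu = np.where(mitotic, p.alpha + p.beta * areas, p.interphase_mean)
    cov = p.noise_sd**2 * np.array([[1, p.noise_rho], [p.noise_rho, 1]])
    eps = rng.multivariate_normal([0, 0], cov, size=len(areas))
    sc = scales[embryos]
    cap = sc * (mu + eps[:, 0])
    cortex = sc * (mu + eps[:, 1])
    return cap, cortex


def _embryo_scales(rng, p: MosaicParams) -> np.ndarray:
    if p.embryo_scales is not None:
        return np.asarray(p.embryo_scales, dtype=float)
    if p.n_embryos == 1:
        return np.ones(1)
    return np.exp(rng.normal(0.0, 0.25, size=p.n_embryos))


def sample_cell_table(params: MosaicParams, seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Table-only sampler (no tessellation or rasters): per-cell group,
    embryo, lognormal apical area and cap/cortex intensities under the
    configured intensity model. Used for statistical-power studies where
    rendered geometry is not needed."""
    rng = np.random.default_rng(seed)
    glabels = list(params.group_props)
    groups = rng.choice(glabels, size=params.n_cells,
                        p=list(params.group_props.values()))
    means = np.array([params.group_means[g] for g in groups])
    sig = params.group_sigma
    areas = np.exp(rng.normal(np.log(means) - sig**2 / 2, sig))
    embryos = rng.integers(0, params.n_embryos, size=params.n_cells)
    scales = _embryo_scales(rng, params)
    cap, cortex = _draw_intensities(rng, areas, groups, embryos, scales, params)
    df = pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(params.n_cells)],
        "embryo_id": [f"e{e}" for e in embryos],
        "group": groups, "area_um2": areas,
        "cap_AU": cap, "cortex_AU": cortex})
    gt = df.assign(true_alpha=params.alpha, true_beta=params.beta,
                   true_scale=scales[embryos])
    return df, GroundTruth("cell_table", gt, asdict(params), seed)


def _poisson_disc(rng, n, x0, x1, y0, y1, r, max_tries=4000):
    """Dart-throwing with a shrinking exclusion radius; exact count."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        if not pts or (np.linalg.norm(np.array(pts) - cand, axis=1) >= r).all():
            pts.append(cand)
            tries = 0
        else:
            tries += 1
            if tries > 200:
                r *= 0.9
                tries = 0
        max_tries -= 1
        if max_tries <= 0:
            raise RuntimeError("seed placement failed")
    return np.array(pts)


def _bounded_voronoi(points: np.ndarray, w: float, h: float) -> list[Polygon]:
    """Voronoi cells clipped to [0,w]x[0,h] via boundary mirroring."""
    mirrors = [points * [-1, 1], points * [1, -1],
               points * [-1, 1] + [2 * w, 0], points * [1, -1] + [0, 2 * h]]
    vor = Voronoi(np.vstack([points] + mirrors))
    rect = box(0, 0, w, h)
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(rect)
        polys.append(poly)
    return polys


def generate_apical_mosaic(
    params: MosaicParams,
    seed: int,
    *,
    render: bool = True,
) -> tuple[pd.DataFrame, np.ndarray | None, np.ndarray | None, GroundTruth]:
    """Voronoi apical mosaic with group-stratified seed densities.

    Cells are seeded by Poisson-disc dart throwing inside horizontal
    strata (one per group, height proportional to the group's share of
    total target area, so mean achieved area tracks the group mean),
    relaxed once by Lloyd's method, and tessellated. Mitotic-group
    intensities follow alpha + beta * area + noise; interphase
    intensities are area-independent. Embryos occupy contiguous vertical
    columns and scale intensities multiplicatively.

    Returns (cells table, label raster, intensity raster, ground truth);
    rasters are None with ``render=False``.
    """
    p = params
    if p.n_cells < 3:
        raise ValueError("need at least 3 cells to tessellate")
    rng = np.random.default_rng(seed)

    glabels = list(p.group_props)
    counts = np.array([int(round(p.n_cells * p.group_props[g])) for g in glabels])
    counts[-1] += p.n_cells - counts.sum()
    total_area = float(sum(c * p.group_means[g] for c, g in zip(counts, glabels)))
    W = p.field_width
    H = total_area / W

    pts_list, groups = [], []
    y0 = 0.0
    for g, n_g in zip(glabels, counts):
        if n_g == 0:
            continue
        h_g = n_g * p.group_means[g] / W
        r_g = 0.8 * np.sqrt(p.group_means[g])
        pts_list.append(_poisson_disc(rng, n_g, 0, W, y0, y0 + h_g, r_g,
                                      max_tries=200 * n_g + 4000))
        groups.extend([g] * n_g)
        y0 += h_g
    points = np.vstack(pts_list)
    groups = np.array(groups)

    # one Lloyd relaxation for realistic packing
    polys = _bounded_voronoi(points, W, H)
    points = np.array([[pl.centroid.x, pl.centroid.y] for pl in polys])
    points = np.clip(points, [1e-6, 1e-6], [W - 1e-6, H - 1e-6])
    polys = _bounded_voronoi(points, W, H)

    areas = np.array([pl.area for pl in polys])
    embryos = np.minimum((points[:, 0] / W * p.n_embryos).astype(int),
                         p.n_embryos - 1)
    scales = _embryo_scales(rng, p)
    cap, cortex = _draw_intensities(rng, areas, groups, embryos, scales, p)

    import json
    verts = [json.dumps(np.asarray(pl.exterior.coords)[:-1].round(4).tolist())
             for pl in polys]
    cells = pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(len(polys))],
        "embryo_id": [f"e{e}" for e in embryos],
        "group": groups, "vertices": verts, "area_um2": areas,
        "cap_AU": cap, "cortex_AU": cortex})

    labels = intensity = None
    if render:
        labels, intensity = _render_mosaic(polys, cap, cortex, p, W, H)

    gt = cells.drop(columns="vertices").assign(
        true_alpha=p.alpha, true_beta=p.beta, true_scale=scales[embryos],
        target_area=[p.group_means[g] for g in groups])
    meta = asdict(p)
    meta.update(field_width_um=W, field_height_um=H)
    return cells, labels, intensity, GroundTruth("mosaic", gt, meta, seed)


def _render_mosaic(polys, cap, cortex, p: MosaicParams, W, H):
    """Piecewise-constant rendering: cortical rim pixels (within
    ``rim_width`` of the cell boundary, inside the cell) carry the cortex
    intensity, interior pixels the cap intensity."""
    from shapely import contains_xy

    px = p.pixel_size
    nx, ny = int(np.ceil(W / px)), int(np.ceil(H / px))
    labels = np.zeros((ny, nx), dtype=np.uint16)
    intensity = np.zeros((ny, nx), dtype=np.float32)
    for i, pl in enumerate(polys):
        minx, miny, maxx, maxy = pl.bounds
        c0, c1 = max(int(minx / px) - 1, 0), min(int(maxx / px) + 2, nx)
        r0, r1 = max(int(miny / px) - 1, 0), min(int(maxy / px) + 2, ny)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        xs, ys = (cc + 0.5) * px, (rr + 0.5) * px
        inside = contains_xy(pl, xs.ravel(), ys.ravel()).reshape(xs.shape)
        inner = pl.buffer(-p.rim_width)
        if inner.is_empty:
            in_core = np.zeros_like(inside)
        else:
            in_core = contains_xy(inner, xs.ravel(), ys.ravel()).reshape(xs.shape)
        rim = inside & ~in_core
        sub_l = labels[r0:r1, c0:c1]
        sub_i = intensity[r0:r1, c0:c1]
        sub_l[inside] = i + 1
        sub_i[in_core] = cap[i]
        sub_i[rim] = cortex[i]
    return labels, intensity


# ---------------------------------------------------------------------------
# live traces

@dataclass
class TraceParams:
    """Pulsatile-trace generator settings (minutes, um^2).

    The mitotic event template: mild dilation from ``dilation_onset`` to
    ``constriction_start`` min before anaphase (peak ``dilation_peak``),
    linear constriction to ``1 - depth`` exactly at the anaphase frame,
    then linear re-dilation to baseline over ``redilation_span`` min.
    Interphase pulsation is mean * (1 + A sin(2 pi t / T + phi)); the
    mitotic sine amplitude is ``amplitude * amplitude_ratio``.
    """

    dt: float = 5.0
    duration: float = 180.0
    mean_area: float = 20.0
    amplitude: float = 0.05            # fraction of mean
    period_range: tuple = (40.0, 80.0)
    dilation_onset: float = 60.0       # min before anaphase
    constriction_start: float = 30.0   # min before anaphase
    depth: float = 0.4                 # fractional minimum at anaphase
    dilation_peak: float = 0.1
    redilation_span: float = 30.0
    amplitude_ratio: float = 2.0       # mitotic / interphase
    noise_sd: float = 0.02             # fraction of mean
    n_mitotic: int = 29
    n_interphase: int = 54

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("frame interval must be > 0")
        if self.duration < 2 * self.period_range[1]:
            raise ValueError("duration must cover >= 2 pulsation periods")
        if self.amplitude_ratio <= 0:
            raise ValueError("mitotic/interphase amplitude ratio must be > 0")
        if not 0 <= self.depth < 1:
            raise ValueError("event depth must be in [0, 1)")
        if self.constriction_start > self.dilation_onset:
            raise ValueError("constriction must start after dilation onset")


def _event_factor(t: np.ndarray, ta: float, p: TraceParams) -> np.ndarray:
    """Piecewise-linear mitotic event multiplier, minimum 1-depth at ta."""
    f = np.ones_like(t)
    t_on, t_c = ta - p.dilation_onset, ta - p.constriction_start
    rise = (t >= t_on) & (t < t_c)
    if t_c > t_on:
        f[rise] = 1 + p.dilation_peak * (t[rise] - t_on) / (t_c - t_on)
    fall = (t >= t_c) & (t <= ta)
    if ta > t_c:
        f[fall] = (1 + p.dilation_peak) - (p.dilation_peak + p.depth) \
            * (t[fall] - t_c) / (ta - t_c)
    redil = (t > ta) & (t <= ta + p.redilation_span)
    f[redil] = (1 - p.depth) + p.depth * (t[redil] - ta) / p.redilation_span
    return f


def generate_traces(
    params: TraceParams, seed: int,
) -> tuple[list[CellTrace], GroundTruth]:
    """Generate mitotic and interphase apical-area traces.

    Anaphase frames are drawn uniformly from sample times that leave the
    full event window inside the trace, so aligned windows span at least
    T0-60 to T0+30 min. A drawn anaphase that would clip the event is
    redrawn (logged in the ground truth as ``redrawn``).
    """
    import logging
    p = params
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, p.duration + p.dt / 2, p.dt)
    ok = (t >= p.dilation_onset) & (t <= p.duration - p.redilation_span)
    if not ok.any():
        raise ValueError("no admissible anaphase frame inside the trace")
    candidates = t[ok]

    traces, rows = [], []
    for i in range(p.n_mitotic + p.n_interphase):
        mitotic = i < p.n_mitotic
        T = rng.uniform(*p.period_range)
        phi = rng.uniform(0, 2 * np.pi)
        A = p.amplitude * (p.amplitude_ratio if mitotic else 1.0)
        base = 1 + A * np.sin(2 * np.pi * t / T + phi)
        ta, redrawn = None, False
        if mitotic:
            ta = float(rng.choice(candidates))
            while ta - p.dilation_onset < -p.dt or ta + p.redilation_span > p.duration + p.dt:
                logging.getLogger(__name__).info(
                    "anaphase window clipped; redrawing cell %d", i)
                ta, redrawn = float(rng.choice(candidates)), True
            base = base * _event_factor(t, ta, p)
        area = p.mean_area * base + rng.normal(0, p.noise_sd * p.mean_area,
                                               size=t.shape)
        cid = f"{'m' if mitotic else 'i'}{i:03d}"
        traces.append(CellTrace(cid, t, area, is_mitotic=mitotic,
                                anaphase_t=ta))
        rows.append({"cell_id": cid, "is_mitotic": mitotic,
                     "true_amplitude": A, "true_period": T, "true_phase": phi,
                     "true_depth": p.depth if mitotic else 0.0,
                     "anaphase_t_min": ta, "redrawn": redrawn})
    return traces, GroundTruth("traces", pd.DataFrame(rows), asdict(p), seed)


# ---------------------------------------------------------------------------
# curved apical profiles

def generate_curved_profile(
    radius: float,
    angle: float,
    n_points: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "",
) -> SurfaceProfile:
    """Ordered points on a circular arc of the given radius and subtended
    angle (centered on the y axis), plus isotropic Gaussian noise. The
    bead-culture geometry motivates radii of roughly 75-106 um."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not 0 < angle < 2 * np.pi:
        raise ValueError("subtended angle must be in (0, 2 pi)")
    if n_points < 3:
        raise ValueError("need >= 3 points")
    rng = np.random.default_rng(seed)
    theta = np.linspace(-angle / 2, angle / 2, n_points)
    pts = radius * np.column_stack([np.sin(theta), np.cos(theta)])
    pts += rng.normal(0, noise_sd, size=pts.shape)
    return SurfaceProfile(pts, sample_id=sample_id,
                          meta={"true_radius_um": radius,
                                "true_angle_rad": angle,
                                "noise_sd_um": noise_sd, "seed": seed})


# ---------------------------------------------------------------------------
# Ki-67 nuclei

@dataclass
class NucleusParams:
    """Ki-67 nucleus generator settings (um).

    ``stage_scale`` scales the ellipsoid semi-axes so mean nuclear volume
    orders earlyG1 < S < G2; M uses the condensed-chromatin mass as its
    mask (nuclear envelope breakdown) with Ki-67 spread over most of it.
    """

    voxel_size: float = 0.3
    base_radii: tuple = (3.6, 3.0, 2.8)   # semi-axes z, y, x
    stage_scale: dict = field(default_factory=lambda: {
        "earlyG1": 0.85, "S": 0.95, "G2": 1.10, "M": 0.80})
    scale_jitter: float = 0.04            # lognormal sigma on the scale
    focus_radius: dict = field(default_factory=lambda: {
        "earlyG1": (0.35, 0.45), "S": (0.95, 1.10), "G2": (1.30, 1.50)})
    n_foci_g1: tuple = (4, 10)
    background: float = 0.1               # Ki-67 AU inside the nucleus
    focus_intensity: float = 1.0
    noise_sd: float = 0.05
    m_coverage: float = 0.85              # Ki-67+ volume fraction in M
    max_retries: int = 2000

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or any(r <= 0 for r in self.base_radii):
            raise ValueError("voxel size and nuclear radii must be > 0")


def _place_disjoint_foci(rng, n_foci, center, radii, lo, hi, p, stage):
    """Rejection-sample disjoint focus spheres inside the ellipsoid; the
    whole placement restarts when a configuration deadlocks, and only
    repeated restarts raise."""
    for _ in range(10):
        placed: list[tuple[np.ndarray, float]] = []
        tries = 0
        while len(placed) < n_foci and tries <= p.max_retries:
            r_f = rng.uniform(lo, hi)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = rng.uniform(0, 1) ** (1 / 3)
            pos = center + u * rad * (radii - r_f - p.voxel_size)
            if all(np.linalg.norm(pos - q) > r_f + rq + 2 * p.voxel_size
                   for q, rq in placed):
                placed.append((pos, float(r_f)))
                tries = 0
            else:
                tries += 1
        if len(placed) == n_foci:
            return placed
    raise RuntimeError(f"focus placement failed for stage {stage}")


def _ellipsoid_mask(shape, center, radii, voxel) -> np.ndarray:
    zz, yy, xx = np.indices(shape)
    coords = (np.stack([zz, yy, xx], axis=-1) + 0.5) * voxel
    d = ((coords - center) / np.asarray(radii)) ** 2
    return d.sum(axis=-1) <= 1.0


def generate_nucleus_stack(
    stage: str,
    params: NucleusParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One synthetic Ki-67 nucleus: (intensity stack, nuclear mask,
    ground truth dict).

    Stage patterns: earlyG1 — 4-10 small disjoint foci; S — two
    condensates; G2 — one punctum; M — bright signal over most of a
    condensed-chromatin mask. Focus placement retries are bounded;
    failure raises.
    """
    p = params or NucleusParams()
    if stage not in STAGE_SET:
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed)
    scale = p.stage_scale[stage] * float(np.exp(rng.normal(0, p.scale_jitter)))
    radii = np.asarray(p.base_radii) * scale
    margin = 0.6
    shape = tuple(int(np.ceil(2 * (r + margin) / p.voxel_size)) for r in radii)
    center = np.array([s * p.voxel_size / 2 for s in shape])
    mask = _ellipsoid_mask(shape, center, radii, p.voxel_size)

    stack = np.zeros(shape, dtype=np.float32)
    stack[mask] = p.background
    foci_truth = []

    if stage == "M":
        core = _ellipsoid_mask(shape, center, radii * p.m_coverage ** (1 / 3),
                               p.voxel_size)
        stack[core & mask] = p.focus_intensity
        foci_truth.append({"kind": "chromatin_spread"})
    else:
        n_foci = {"earlyG1": int(rng.integers(p.n_foci_g1[0],
                                              p.n_foci_g1[1] + 1)),
                  "S": 2, "G2": 1}[stage]
        lo, hi = p.focus_radius[stage]
        if stage == "S":
            # two condensates on opposite sides of the nucleus
            r1, r2 = rng.uniform(lo, hi, size=2)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)

            def _extent(r_f, u):  # reach along u inside the shrunk ellipsoid
                A = radii - r_f - p.voxel_size
                return 1.0 / np.sqrt(((u / A) ** 2).sum())

            sep_needed = r1 + r2 + 2 * p.voxel_size
            s = 0.8
            if s * (_extent(r1, u) + _extent(r2, u)) < sep_needed:
                u = np.eye(3)[int(np.argmax(radii))]  # long axis fallback
            placed = [
                (center + s * _extent(r1, u) * u, float(r1)),
                (center - s * _extent(r2, u) * u, float(r2)),
            ]
        else:
            placed = _place_disjoint_foci(rng, n_foci, center, radii,
                                          lo, hi, p, stage)
        for pos, r_f in placed:
            sphere = _ellipsoid_mask(shape, pos, (r_f,) * 3, p.voxel_size)
            stack[sphere & mask] = p.focus_intensity
            foci_truth.append({"center_um": pos.tolist(),
                               "radius_um": float(r_f)})

    if p.noise_sd > 0:
        stack = stack + rng.normal(0, p.noise_sd,
                                   size=shape).astype(np.float32)

    voxel_vol = p.voxel_size ** 3
    gt = {"stage": stage, "seed": int(seed), "scale": float(scale),
          "radii_um": radii.tolist(),
          "volume_um3": float(mask.sum() * voxel_vol),
          "condensed": stage == "M", "n_foci": len(foci_truth),
          "foci": foci_truth}
    return stack, mask, gt


STAGE_SET = frozenset({"earlyG1", "S", "G2", "M"})


def generate_nucleus_panel(
    stages: dict[str, int],
    params: NucleusParams | None = None,
    seed: int = 0,
) -> tuple[list[tuple[np.ndarray, np.ndarray, dict]], GroundTruth]:
    """Generate a panel of nuclei (stage -> count) with one ground-truth
    record per nucleus, seeds derived deterministically from ``seed``."""
    p = params or NucleusParams()
    out, rows = [], []
    k = 0
    for stage, n in stages.items():
        for _ in range(n):
            sub = (seed * 100003 + k) % (2**31 - 1)
            stack, mask, gt = generate_nucleus_stack(stage, p, sub)
            gt["nucleus_id"] = f"n{k:03d}"
            out.append((stack, mask, gt))
            rows.append({k2: v for k2, v in gt.items() if k2 != "foci"})
            k += 1
    return out, GroundTruth("nuclei", pd.DataFrame(rows), asdict(p), seed)
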