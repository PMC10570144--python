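"""Ki-67 foci-based cell-cycle staging and nuclear morphometry.

Ki-67 redistributes through interphase in a stereotyped sequence: many
small nucleolar-associated foci in early G1, two condensates in S, a
single punctum in G2, then spreading over the condensing chromosomes at
mitotic entry. Stage is therefore called from the number and relative
size of detected foci plus a condensed-chromatin annotation; nuclear
volume (smallest in early G1, largest in G2) serves as an independent
surrogate of cell-cycle progression.

Numeric thresholds (f_M, v_S, v_G1, n_G1, Otsu thresholding) are
engineering defaults exposed in StagingThresholds; the underlying staining
patterns are qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

STAGES = ("earlyG1", "S", "G2", "M")


@dataclass
class StagingThresholds:
    f_M: float = 0.5       # min Ki-67+ volume fraction for M (with condensation)
    v_S: float = 0.02      # min focus volume fraction for an S condensate
    v_G1: float = 0.01     # max focus volume fraction for an early-G1 focus
    n_G1: int = 4          # min focus count for early G1
    min_focus_voxels: int = 2
    threshold: str | float = "otsu"


@dataclass
class Focus:
    centroid_um: tuple[float, float, float]
    volume_um3: float
    mean_AU: float


@dataclass
class NucleusRecord:
    nucleus_id: str
    stage: str  # earlyG1 | S | G2 | M | unclassified
    foci: list[Focus] = field(default_factory=list)
    volume_um3: float = 0.0
    positive_fraction: float = 0.0
    apical_distance_um: float | None = None
    condensed: bool = False

    def to_dict(self) -> dict:
        return {"nucleus_id": self.nucleus_id, "stage": self.stage,
                "n_foci": len(self.foci), "volume_um3": self.volume_um3,
                "positive_fraction": self.positive_fraction,
                "apical_distance_um": self.apical_distance_um,
                "condensed": self.condensed}


def detect_foci(
    stack: np.ndarray,
    mask: np.ndarray,
    voxel_size: float | tuple[float, float, float],
    *,
    threshold: str | float = "otsu",
    min_volume_voxels: int = 2,
) -> tuple[list[Focus], float]:
    """Connected components (26-connectivity) of supra-threshold voxels
    inside the nuclear mask.

    ``threshold`` is either a fixed intensity or ``"otsu"`` (computed over
    the masked voxels). Components below ``min_volume_voxels`` are
    discarded. Returns the foci plus the Ki-67-positive volume fraction of
    the mask (before the size filter).
    """
    if not mask.any():
        raise ValueError("empty nuclear mask")
    if stack.shape != mask.shape:
        raise ValueError("stack and mask shapes differ")
    vz, vy, vx = (voxel_size,) * 3 if np.isscalar(voxel_size) else voxel_size
    voxel_vol = vz * vy * vx

    vals = stack[mask]
    if threshold == "otsu":
        from skimage.filters import threshold_otsu
        if vals.max() == vals.min():
            return [], 0.0
        thr = float(threshold_otsu(vals))
    else:
        thr = float(threshold)
    positive = (stack > thr) & mask
    frac = float(positive.sum() / mask.sum())
    if not positive.any():
        return [], 0.0

    labels, n = ndimage.label(positive, structure=np.ones((3, 3, 3), dtype=int))
    foci: list[Focus] = []
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    centroids = ndimage.center_of_mass(positive, labels, range(1, n + 1))
    means = ndimage.mean(stack, labels, range(1, n + 1))
    for size, com, mean in zip(sizes, centroids, means):
        if size < min_volume_voxels:
            continue
        foci.append(Focus(
            centroid_um=(com[0] * vz, com[1] * vy, com[2] * vx),
            volume_um3=float(size * voxel_vol),
            mean_AU=float(mean)))
    return foci, frac


def classify_stage(
    foci: list[Focus],
    nuclear_volume_um3: float,
    positive_fraction: float,
    condensed: bool,
    thresholds: StagingThresholds | None = None,
) -> str:
    """Rule-based stage call from the Ki-67 pattern.

    Order: M (condensed chromatin and positive fraction > f_M), then G2
    (exactly one focus), S (exactly two foci, each above v_S of nuclear
    volume), early G1 (at least n_G1 foci, each below v_G1). Anything else
    is "unclassified" — a value, not an error.
    """
    th = thresholds or StagingThresholds()
    if nuclear_volume_um3 <= 0:
        raise ValueError("nuclear volume must be > 0")
    if condensed and positive_fraction > th.f_M:
        return "M"
    if len(foci) == 1:
        return "G2"
    fracs = [f.volume_um3 / nuclear_volume_um3 for f in foci]
    if len(foci) == 2 and all(f > th.v_S for f in fracs):
        return "S"
    if len(foci) >= th.n_G1 and all(f < th.v_G1 for f in fracs):
        return "earlyG1"
    return "unclassified"


def nuclear_volume(mask: np.ndarray,
                   voxel_size: float | tuple[float, float, float]) -> float:
    """Voxel count times voxel volume (um^3); additive over disjoint masks."""
    if not mask.any():
        raise ValueError("empty nuclear mask")
    vz, vy, vx = (voxel_size,) * 3 if np.isscalar(voxel_size) else voxel_size
    return float(mask.sum() * vz * vy * vx)


def apical_distance(
    centroid: np.ndarray,
    reference: float | np.ndarray,
    *,
    axis: int = 0,
) -> float:
    """Unsigned distance from a nuclear centroid to the apical surface.

    ``reference`` is either a scalar plane coordinate (perpendicular
    distance along ``axis``, default the z axis) or an ordered polyline
    (N x d array; nearest point over all segments).
    """
    c = np.asarray(centroid, dtype=float)
    if np.isscalar(reference) or np.ndim(reference) == 0:
        return float(abs(c[axis] - float(reference)))
    line = np.asarray(reference, dtype=float)
    if line.ndim != 2 or len(line) < 2:
        raise ValueError("polyline reference needs >= 2 points")
    p = c[: line.shape[1]]
    a, b = line[:-1], line[1:]
    ab = b - a
    tt = np.clip(np.einsum("ij,ij->i", p - a, ab)
                 / np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-300), 0, 1)
    proj = a + tt[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


def stage_nucleus(
    stack: np.ndarray,
    mask: np.ndarray,
    voxel_size: float | tuple[float, float, float],
    *,
    nucleus_id: str = "",
    condensed: bool = False,
    apical_reference: float | np.ndarray | None = None,
    thresholds: StagingThresholds | None = None,
) -> NucleusRecord:
    """Full per-nucleus pipeline: foci detection, volume, stage call and
    (optionally) apical distance from the mask centroid."""
    th = thresholds or StagingThresholds()
    foci, frac = detect_foci(stack, mask, voxel_size,
                             threshold=th.threshold,
                             min_volume_voxels=th.min_focus_voxels)
    vol = nuclear_volume(mask, voxel_size)
    stage = classify_stage(foci, vol, frac, condensed, th)
    dist = None
    if apical_reference is not None:
        vz, vy, vx = ((voxel_size,) * 3 if np.isscalar(voxel_size)
                      else voxel_size)
        com = ndimage.center_of_mass(mask)
        centroid = np.array([com[0] * vz, com[1] * vy, com[2] * vx])
        dist = apical_distance(centroid, apical_reference)
    return NucleusRecord(nucleus_id=nucleus_id, stage=stage, foci=foci,
                         volume_um3=vol, positive_fraction=frac,
                         apical_distance_um=dist, condensed=condensed)


def stage_summary(records: list[NucleusRecord] | pd.DataFrame,
                  *, merge_g1s: bool = True) -> pd.DataFrame:
    """Per-stage n, mean/median nuclear volume, mean apical distance and
    stage proportions.

    With ``merge_g1s`` (default, matching how G1 and S are usually pooled
    in apical-area comparisons) early G1 and S report as "G1/S"; the
    volume-ordering flag (mean volume earlyG1 < S < G2) is always
    evaluated on the unmerged stages and stored in ``attrs['volume_ordering_ok']``.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.to_dict() for r in records])
    if df.empty:
        raise ValueError("no nucleus records")

    means = df.groupby("stage")["volume_um3"].mean()
    ordering = all(s in means.index for s in ("earlyG1", "S", "G2")) and \
        means.get("earlyG1", np.inf) < means.get("S", -np.inf) < means.get("G2", -np.inf)

    if merge_g1s:
        df["stage"] = df["stage"].replace({"earlyG1": "G1/S", "S": "G1/S"})
    out = (df.groupby("stage")
           .agg(n=("nucleus_id", "size"),
                mean_volume_um3=("volume_um3", "mean"),
                median_volume_um3=("volume_um3", "median"),
                mean_apical_distance_um=("apical_distance_um", "mean"))
           .reset_index())
    out["proportion"] = out["n"] / out["n"].sum()
    out.attrs["volume_ordering_ok"] = bool(ordering)
    return out


def nuclear_index(thickness_um: float, mean_nuclear_extent_um: float) -> float:
    """Pseudo-row count: epithelial thickness over mean apicobasal nuclear
    extent, to one decimal (a pseudostratified neuroepithelium packs about
    three such rows)."""
    if thickness_um <= 0 or mean_nuclear_extent_um <= 0:
        raise ValueError("thickness and nuclear extent must be > 0")
    return round(thickness_um / mean_nuclear_extent_um, 1)
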