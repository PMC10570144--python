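"""File I/O for the pipeline's standard table and raster formats.

Tables are UTF-8 CSV with a header row and "." decimals; polygons travel
as JSON strings of [x, y] vertex lists in um; rasters are TIFF (16-bit
label images, 32-bit float intensities); profiles are JSON lists of
[x, y]; configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .curvature import SurfaceProfile
from .pulses import CellTrace


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_raster(raster: np.ndarray, path) -> None:
    tifffile.imwrite(path, raster)


def read_raster(path) -> np.ndarray:
    return tifffile.imread(path)


def write_traces(traces: list[CellTrace], path) -> None:
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id, "t_min": tr.t, "area_um2": tr.area,
            "is_mitotic": tr.is_mitotic,
            "anaphase_t_min": tr.anaphase_t if tr.anaphase_t is not None
            else np.nan}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[CellTrace]:
    df = pd.read_csv(path)
    traces = []
    for cid, g in df.groupby("cell_id", sort=False):
        mitotic = bool(g["is_mitotic"].iloc[0])
        ana = g["anaphase_t_min"].iloc[0]
        traces.append(CellTrace(
            str(cid), g["t_min"].to_numpy(), g["area_um2"].to_numpy(),
            is_mitotic=mitotic,
            anaphase_t=float(ana) if mitotic and np.isfinite(ana) else None))
    return traces


def write_profile(profile: SurfaceProfile, path) -> None:
    with open(path, "w") as fh:
        json.dump({"sample_id": profile.sample_id,
                   "points_um": profile.points.tolist(),
                   "meta": profile.meta}, fh)


def read_profile(path) -> SurfaceProfile:
    with open(path) as fh:
        d = json.load(fh)
    return SurfaceProfile(np.asarray(d["points_um"]),
                          sample_id=d.get("sample_id", ""),
                          meta=d.get("meta", {}))


def write_nuclei(nuclei: list[tuple[np.ndarray, np.ndarray, dict]],
                 directory) -> None:
    """One multi-page TIFF pair (signal, mask) per nucleus plus a
    nuclei.csv manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for stack, mask, gt in nuclei:
        nid = gt["nucleus_id"]
        tifffile.imwrite(directory / f"{nid}_ki67.tif", stack)
        tifffile.imwrite(directory / f"{nid}_mask.tif",
                         mask.astype(np.uint8))
        rows.append({"nucleus_id": nid, "stage": gt["stage"],
                     "condensed_flag": gt["condensed"]})
    pd.DataFrame(rows).to_csv(directory / "nuclei.csv", index=False)


def read_nuclei(directory) -> list[tuple[np.ndarray, np.ndarray, dict]]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "nuclei.csv")
    out = []
    for _, row in manifest.iterrows():
        nid = row["nucleus_id"]
        stack = tifffile.imread(directory / f"{nid}_ki67.tif")
        mask = tifffile.imread(directory / f"{nid}_mask.tif").astype(bool)
        out.append((stack, mask, {"nucleus_id": nid,
                                  "stage": row.get("stage"),
                                  "condensed": bool(row["condensed_flag"])}))
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
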