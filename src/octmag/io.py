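"""Readers and writers for the package's on-disk formats.

Biometry travels as CSV; scan geometry as a JSON sidecar; thickness maps
and segmented surfaces as NPZ array containers (or CSV long format for tiny
hand-written fixtures); sector means and effect tables as tidy CSV.  The
synthetic generator writes exactly the schema the real-data path reads, so
the two are interchangeable downstream.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ScanGeometry
from .thickness import SegmentedSurfaces, ThicknessMap

__all__ = [
    "BIOMETRY_COLUMNS", "read_biometry", "write_biometry",
    "read_geometry", "write_geometry",
    "save_surfaces", "load_surfaces", "surfaces_from_long_csv",
    "save_thickness_map", "load_thickness_map",
    "write_sector_table", "read_sector_table",
    "write_json", "read_json",
]

BIOMETRY_COLUMNS = ["participant_id", "eye", "axial_length_mm",
                    "corneal_radius_mm", "sphere_d", "cylinder_d", "snr",
                    "sex", "ethnicity"]


def read_biometry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(BIOMETRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"biometry CSV missing columns: {sorted(missing)}")
    return df


def write_biometry(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(BIOMETRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"biometry frame missing columns: {sorted(missing)}")
    df.to_csv(path, index=False)


def write_geometry(geometry: ScanGeometry, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(geometry), indent=2) + "\n")


def read_geometry(path: str | Path) -> ScanGeometry:
    return ScanGeometry(**json.loads(Path(path).read_text()))


def save_surfaces(surfaces: SegmentedSurfaces, path: str | Path) -> None:
    np.savez(path, ilm=surfaces.ilm, rpe=surfaces.rpe,
             unit=np.array(surfaces.unit))


def load_surfaces(path: str | Path, geometry: ScanGeometry,
                  ) -> SegmentedSurfaces:
    with np.load(path) as z:
        return SegmentedSurfaces(ilm=z["ilm"], rpe=z["rpe"],
                                 geometry=geometry, unit=str(z["unit"]))


def surfaces_from_long_csv(path: str | Path, geometry: ScanGeometry,
                           unit: str = "px") -> SegmentedSurfaces:
    """Tiny-fixture format: columns bscan, ascan, ilm, rpe (one row per
    A-scan; absent A-scans become NaN)."""
    df = pd.read_csv(path)
    shape = (geometry.n_bscans, geometry.n_ascans)
    ilm = np.full(shape, np.nan)
    rpe = np.full(shape, np.nan)
    i = df["bscan"].to_numpy(int)
    j = df["ascan"].to_numpy(int)
    ilm[i, j] = df["ilm"].to_numpy(float)
    rpe[i, j] = df["rpe"].to_numpy(float)
    return SegmentedSurfaces(ilm=ilm, rpe=rpe, geometry=geometry, unit=unit)


def save_thickness_map(tmap: ThicknessMap, path: str | Path) -> None:
    extra = {}
    if tmap.fovea_centre is not None:
        extra["fovea_centre"] = np.asarray(tmap.fovea_centre)
    np.savez(path, thickness=tmap.thickness, valid_mask=tmap.valid_mask,
             **extra)


def load_thickness_map(path: str | Path, geometry: ScanGeometry,
                       ) -> ThicknessMap:
    with np.load(path) as z:
        centre = tuple(z["fovea_centre"]) if "fovea_centre" in z else None
        return ThicknessMap(thickness=z["thickness"],
                            valid_mask=z["valid_mask"],
                            geometry=geometry, fovea_centre=centre)


def write_sector_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_sector_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    df["corrected"] = df["corrected"].astype(bool)
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
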