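"""Readers and writers for the standard on-disk formats.

NIfTI-1 (``.nii`` / ``.nii.gz``) for volumes via nibabel; UTF-8 TSV with an
``NA`` missing marker for tables; a 3-column events TSV (onset, duration,
condition) for task designs; a 6-column TSV for realignment traces.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import VolumeSeries
from .task import TaskDesign

NA = "NA"


def save_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_volume(path) -> tuple:
    """Load a 3D/4D NIfTI; returns (data, affine, voxel_size)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D NIfTI, got {img.ndim}D")
    data = np.asarray(img.get_fdata(), dtype=float)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine, dtype=float), voxel_size


def save_series(path, series: VolumeSeries, realignment_path=None) -> None:
    save_volume(path, series.data, series.affine)
    if realignment_path is not None:
        save_realignment(realignment_path, series.realignment)


def load_series(path, realignment_path) -> VolumeSeries:
    data, affine, voxel_size = load_volume(path)
    realignment = load_realignment(realignment_path)
    return VolumeSeries(
        data=data, voxel_size=voxel_size, affine=affine, realignment=realignment
    )


REALIGN_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def save_realignment(path, realignment: np.ndarray) -> None:
    pd.DataFrame(realignment, columns=REALIGN_COLS).to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


def load_realignment(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    if list(df.columns) != REALIGN_COLS:
        raise ValueError(f"realignment TSV must have columns {REALIGN_COLS}")
    return df.to_numpy(dtype=float)


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def save_cohort(path, cohort: pd.DataFrame) -> None:
    save_table(path, cohort)


def load_cohort(path) -> pd.DataFrame:
    df = load_table(path)
    if df["child_id"].duplicated().any():
        dupes = df["child_id"][df["child_id"].duplicated()].tolist()
        raise ValueError(f"duplicate child_id values: {dupes}")
    return df


def save_events(path, design: TaskDesign) -> None:
    rows = [{"onset": o, "duration": d, "condition": c} for c, o, d in design.events]
    pd.DataFrame(rows, columns=["onset", "duration", "condition"]).to_csv(
        path, sep="\t", index=False
    )


def load_events(path) -> list:
    df = pd.read_csv(path, sep="\t")
    needed = {"onset", "duration", "condition"}
    if not needed <= set(df.columns):
        raise ValueError(f"events TSV must have columns {sorted(needed)}")
    return [
        (str(r.condition), float(r.onset), float(r.duration))
        for r in df.itertuples(index=False)
    ]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
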