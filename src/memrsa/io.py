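"""Readers and writers for the pipeline's tabular and volumetric formats.

Tables are TSV/CSV with a header row; volumes are single-file NIfTI-1.
Voxel indexing is the 0-based (x, y, z) triple of the array; the affine is
carried through untouched.  All writers round-trip losslessly (exactly for
tables, to <= 1e-6 for float volumes).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ShapeError
from .scoring import WorkerResponseLog, validate_memorability_table
from .volume import StatMap

RESPONSE_LOG_COLUMNS = ["worker_id", "position", "image_id", "is_repeat", "pressed"]
TRIAL_TABLE_COLUMNS = ["subject_id", "trial", "image_id", "history", "response", "onset_tr"]


# --- response logs ---------------------------------------------------------

def write_response_log(logs: list[WorkerResponseLog], path) -> None:
    frames = []
    for log in logs:
        df = log.events.copy()
        df.insert(0, "worker_id", log.worker_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["is_repeat"] = out["is_repeat"].astype(int)
    out["pressed"] = out["pressed"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_response_log(path) -> list[WorkerResponseLog]:
    """Parse a worker response-log TSV into one log per worker.

    Requires columns worker_id, position, image_id, is_repeat, pressed;
    extra columns (role, lag) are preserved.  Duplicate (worker, position)
    pairs violate stream integrity.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(RESPONSE_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(subset=["worker_id", "position"]).any():
        raise IntegrityError(f"{path}: duplicate (worker, position) rows")
    df["is_repeat"] = df["is_repeat"].astype(bool)
    df["pressed"] = df["pressed"].astype(bool)
    if "role" not in df.columns:
        df["role"] = "target"
    if "lag" not in df.columns:
        df["lag"] = np.nan
    logs = []
    for wid, grp in df.groupby("worker_id", sort=True):
        logs.append(
            WorkerResponseLog(
                worker_id=str(wid),
                events=grp.drop(columns="worker_id").reset_index(drop=True),
            )
        )
    return logs


# --- trial tables ----------------------------------------------------------

def write_trial_tables(tables: dict[str, pd.DataFrame], path) -> None:
    out = pd.concat(tables.values(), ignore_index=True)
    out.to_csv(path, sep="\t", index=False)


def read_trial_tables(path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(subset=["subject_id", "image_id"]).any():
        raise IntegrityError(f"{path}: a (subject, image) pair appears twice")
    if "remembered" in df.columns:
        df["remembered"] = df["remembered"].astype(bool)
    return {str(sid): grp.reset_index(drop=True) for sid, grp in df.groupby("subject_id", sort=True)}


# --- memorability tables ---------------------------------------------------

def write_memorability_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="image_id")


def read_memorability_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="image_id")
    missing = {"HR", "FA", "Pr", "dprime", "n_hr", "n_fa"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    validate_memorability_table(df)
    return df


# --- volumes ---------------------------------------------------------------

def read_volume(path, expect_3d: bool = False):
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if expect_3d and data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    return data, img.affine


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    data, affine = read_volume(path, expect_3d=True)
    return data > 0.5, affine


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine if affine is not None else np.eye(4)), str(path))


def write_map(stat_map: StatMap, path) -> None:
    """Write a StatMap as NIfTI with out-of-mask (and undefined) voxels at 0;
    save the mask alongside as ``<stem>_mask.nii``."""
    path = Path(path)
    write_volume(stat_map.to_volume(fill=0.0), path, stat_map.affine)
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    write_volume(stat_map.mask.astype(np.float32), mask_path, stat_map.affine)


def read_map(path, mask: np.ndarray | None = None, value_kind: str = "other") -> StatMap:
    data, affine = read_volume(path, expect_3d=True)
    if mask is None:
        path = Path(path)
        mask, _ = read_mask(path.with_name(path.name.replace(".nii", "_mask.nii")))
    if mask.shape != data.shape:
        raise ShapeError(f"{path}: mask shape {mask.shape} != volume shape {data.shape}")
    return StatMap.from_volume(data, mask, value_kind=value_kind, affine=affine)


# --- pattern matrices ------------------------------------------------------

def write_patterns(pattern_set, path) -> None:
    """Trials-by-voxels matrix as TSV with voxel-coordinate header columns."""
    cols = ["x%d_%d_%d" % tuple(c) for c in pattern_set.voxel_coords]
    df = pd.DataFrame(pattern_set.patterns, columns=cols)
    df.insert(0, "trial", pattern_set.trial_index)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_patterns(path, grid_shape):
    from .prep import TrialPatternSet

    df = pd.read_csv(path, sep="\t")
    trial_index = df.pop("trial").to_numpy()
    coords = np.array([[int(p) for p in c[1:].split("_")] for c in df.columns])
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    mask[tuple(coords.T)] = True
    # column order must match the C-order mask scan
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    return TrialPatternSet(
        patterns=df.to_numpy()[:, order],
        mask=mask,
        grid_shape=tuple(grid_shape),
        trial_index=trial_index,
    )
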