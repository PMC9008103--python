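"""NIfTI, schedule-table and config I/O.

Images travel as NIfTI-1 with voxel spacing taken from the header
``pixdim``; 4D files carry frames on the fourth axis.  Frame schedules
and TACs are tab-delimited text.  Run configuration is YAML.  Axes are
assumed RAS-aligned (no oblique handling); images are written with a
diagonal affine.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .harmonization import DynamicImage
from .image import Image3D
from .kinetics import FrameSchedule, TAC

log = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_image",
    "read_dynamic",
    "read_schedule",
    "write_schedule",
    "read_tac",
    "write_tac",
    "read_config",
    "write_manifest",
]


def _load_nifti(path):
    path = Path(path)
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel wraps many header failures
        raise ValueError(f"{path}: not a readable NIfTI-1 file ({exc})") from exc
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: header field pixdim has non-positive spacing {zooms}")
    return img, tuple(float(z) for z in zooms)


def read_image(path) -> Image3D:
    """Read a 3D NIfTI volume; spacing comes from the header pixdim."""
    img, spacing = _load_nifti(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {data.shape}; "
            "use read_dynamic for 4D files"
        )
    return Image3D(data, spacing)


def read_dynamic(path, schedule: FrameSchedule) -> DynamicImage:
    """Read a 4D NIfTI series whose frame count matches the schedule."""
    img, spacing = _load_nifti(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    if data.shape[3] != schedule.n_frames:
        raise ValueError(
            f"{path}: file has {data.shape[3]} frames but the schedule has "
            f"{schedule.n_frames}"
        )
    return DynamicImage(data, spacing, schedule)


def write_image(obj, path):
    """Write an Image3D or DynamicImage as float32 NIfTI-1 with a
    diagonal affine built from the voxel spacing."""
    if isinstance(obj, DynamicImage):
        data, spacing = obj.values, obj.spacing
    else:
        data, spacing = obj.values, obj.spacing
    affine = np.diag(list(spacing) + [1.0])
    nifti = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nifti.header.set_zooms(tuple(spacing) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(nifti, str(path))


def read_schedule(path) -> FrameSchedule:
    """Read a frame table (tab-delimited, columns start_min duration_min);
    contiguity is validated and the offending frame named on failure."""
    df = pd.read_csv(path, sep="\t")
    for col in ("start_min", "duration_min"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    starts = df["start_min"].to_numpy(dtype=float)
    durs = df["duration_min"].to_numpy(dtype=float)
    for i in range(len(starts) - 1):
        gap = starts[i] + durs[i] - starts[i + 1]
        if abs(gap) > 1e-9:
            kind = "overlaps" if gap > 0 else "leaves a gap before"
            raise ValueError(f"{path}: frame {i} {kind} frame {i + 1}")
    return FrameSchedule(tuple(starts), tuple(durs))


def write_schedule(schedule: FrameSchedule, path):
    pd.DataFrame(
        {"start_min": schedule.frame_starts, "duration_min": schedule.frame_durations}
    ).to_csv(path, sep="\t", index=False)


def read_tac(path) -> TAC:
    """Read a TAC table (columns frame_start_min, frame_duration_min,
    value_Bq_per_mL)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("frame_start_min", "frame_duration_min", "value_Bq_per_mL"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    schedule = FrameSchedule(
        tuple(df["frame_start_min"].astype(float)),
        tuple(df["frame_duration_min"].astype(float)),
    )
    return TAC(schedule, df["value_Bq_per_mL"].to_numpy(dtype=float))


def write_tac(tac: TAC, path):
    pd.DataFrame(
        {
            "frame_start_min": tac.schedule.frame_starts,
            "frame_duration_min": tac.schedule.frame_durations,
            "value_Bq_per_mL": tac.values,
        }
    ).to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_manifest(path, **entries):
    """Write a run manifest (config, seeds, package version) as YAML."""
    from . import __version__

    manifest = {"petharm_version": __version__}
    manifest.update(entries)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
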