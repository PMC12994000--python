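"""On-disk formats: NIfTI volumes, array containers, delimited tables.

BOLD data and masks travel as NIfTI-1 (4D float data, 3D masks binarized
at 0.5); frame logs and feature stores are versioned .npz containers;
motion parameters are 6-column plain-text tables with one row per volume.
Voxel indices are 0-based grid indices throughout; world coordinates exist
only through the stored affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .design import VoxelSeries
from .frames import FrameSequence
from .network import FeatureTimeSeries

FRAME_STORE_VERSION = 1
FEATURE_STORE_VERSION = 1


# ---------------------------------------------------------------- NIfTI

def write_bold(values_4d: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values_4d, dtype=np.float32), affine), str(path))


def read_mask(path, threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D mask, binarizing at ``threshold``. Returns (mask, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask {path} must be 3D, got {data.ndim}D")
    return data > threshold, img.affine


def read_bold(path, mask_path=None, expected_volumes: int | None = None) -> VoxelSeries:
    """Read a 4D BOLD file into a VoxelSeries (optionally within a mask)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"BOLD file {path} must be 4D, got {data.ndim}D")
    if expected_volumes is not None and data.shape[3] != expected_volumes:
        raise ValueError(
            f"{path}: {data.shape[3]} volumes found, config expects {expected_volumes}"
        )
    if mask_path is not None:
        mask, mask_affine = read_mask(mask_path)
        if not np.allclose(mask_affine, img.affine, atol=1e-4):
            raise ValueError(f"affine mismatch between BOLD {path} and mask {mask_path}")
        if mask.shape != data.shape[:3]:
            raise ValueError(f"grid mismatch between BOLD {path} and mask {mask_path}")
        coords = np.argwhere(mask)
    else:
        coords = np.argwhere(np.ones(data.shape[:3], dtype=bool))
    values = data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    return VoxelSeries(values, coords, mask_id=str(mask_path or "whole"))


def write_map(
    voxel_values: np.ndarray,
    voxel_coordinates: np.ndarray,
    volume_shape: tuple,
    affine: np.ndarray,
    path,
    fill: float = 0.0,
) -> None:
    """Scatter per-voxel values back into a 3D volume and save as NIfTI."""
    vol = np.full(volume_shape, fill, dtype=np.float32)
    c = np.asarray(voxel_coordinates, dtype=int)
    vol[c[:, 0], c[:, 1], c[:, 2]] = voxel_values
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------- stores

def write_frames(seq: FrameSequence, path) -> None:
    np.savez_compressed(
        path, version=FRAME_STORE_VERSION, frames=seq.frames,
        terminal_flags=seq.terminal_flags, actions=seq.actions,
        rewards=seq.rewards, rate_hz=seq.rate_hz,
    )


def read_frames(path) -> FrameSequence:
    with np.load(path, allow_pickle=False) as z:
        if int(z["version"]) != FRAME_STORE_VERSION:
            raise ValueError(f"unsupported frame store version {z['version']}")
        return FrameSequence(
            z["frames"], z["terminal_flags"], z["actions"], z["rewards"],
            float(z["rate_hz"]),
        )


def write_features(f: FeatureTimeSeries, path) -> None:
    np.savez_compressed(
        path, version=FEATURE_STORE_VERSION, values=f.values,
        unit_layer=f.unit_layer.astype("U16"), rate_hz=f.rate_hz,
    )


def read_features(path) -> FeatureTimeSeries:
    with np.load(path, allow_pickle=False) as z:
        if int(z["version"]) != FEATURE_STORE_VERSION:
            raise ValueError(f"unsupported feature store version {z['version']}")
        return FeatureTimeSeries(z["values"], z["unit_layer"], float(z["rate_hz"]))


def write_motion(motion: np.ndarray, path) -> None:
    """6-column text table, one row per volume."""
    np.savetxt(path, np.asarray(motion, dtype=float).T, fmt="%.8f")


def read_motion(path) -> np.ndarray:
    """Returns parameters x volumes."""
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion table {path} must have 6 columns")
    return m.T


def write_manifest(path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True, default=str))
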