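"""Volumetric and tabular I/O.

Volumes are written as NIfTI (voxel spacing in the header, mm); profiles as
CSV; run summaries as JSON sidecars.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .optics import VoxelGrid

__all__ = ["write_volume", "read_volume", "write_profile_csv", "read_profile_csv"]


def write_volume(path, values: np.ndarray, grid: VoxelGrid) -> Path:
    """Write a 3-D field on ``grid`` as NIfTI with mm voxel spacing."""
    path = Path(path)
    mm = grid.voxel_size * 10.0
    affine = np.diag([mm, mm, mm, 1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    img.header.set_zooms((mm, mm, mm))
    nib.save(img, str(path))
    return path


def read_volume(path):
    """Read a NIfTI volume; returns (values, voxel_size_cm)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"{path}: anisotropic voxels {zooms} not supported")
    return np.asarray(img.get_fdata()), float(zooms[0]) / 10.0


def write_profile_csv(path, profile: np.ndarray) -> Path:
    """Write a centreline profile (depth_cm, phi_mW_per_cm2, ratio) as CSV."""
    cols = ["depth_cm", "phi_mW_per_cm2", "ratio"][: profile.shape[1]]
    pd.DataFrame(profile, columns=cols).to_csv(path, index=False)
    return Path(path)


def read_profile_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
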