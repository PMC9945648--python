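"""NIfTI / CSV helpers shared by the CLI and scripts."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["save_nifti", "load_nifti", "save_param_table", "load_param_table"]


def save_nifti(array: np.ndarray, path, voxel_mm: float = 0.156) -> None:
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def save_param_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_param_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
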