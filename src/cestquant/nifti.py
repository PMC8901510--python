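"""Thin NIfTI I/O helpers used by the pipeline and CLI.

All volumes are NIfTI-1 via nibabel.  Inputs that must live on the same
grid (series, S0, masks) are validated for matching shape and affine.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume", "load_mask", "check_same_grid"]


def save_volume(data: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> Path:
    """Write an array as uncompressed NIfTI-1 (deterministic bytes)."""
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_data_dtype(np.float64 if np.issubdtype(
        np.asarray(data).dtype, np.floating) else np.asarray(data).dtype)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path):
    """Return ``(data, affine)`` of a NIfTI file."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def load_mask(path: str | Path) -> np.ndarray:
    data, _ = load_volume(path)
    return np.asarray(data) > 0


def check_same_grid(shapes_affines: list[tuple], names: list[str]) -> None:
    """Raise if any input differs in spatial shape or affine."""
    (shape0, aff0), name0 = shapes_affines[0], names[0]
    for (shape, aff), name in zip(shapes_affines[1:], names[1:]):
        if tuple(shape[:3]) != tuple(shape0[:3]):
            raise ValueError(f"{name} grid {shape[:3]} != {name0} grid {shape0[:3]}")
        if not np.allclose(aff, aff0, atol=1e-6):
            raise ValueError(f"{name} affine differs from {name0}")
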