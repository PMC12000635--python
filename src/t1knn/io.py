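"""NIfTI-1 volume I/O and grid bookkeeping."""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "check_same_grid", "file_sha256"]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D NIfTI volume (plain or gzipped).

    Returns ``(data, affine)``; the data are float64 and must be finite.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite values")
    return data, img.affine


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D volume as NIfTI-1; round trips bit-exactly for float64."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    out = data.astype(np.float64) if data.dtype != np.float64 else data
    img = nib.Nifti1Image(out, affine)
    nib.save(img, str(path))


def check_same_grid(named_shapes: dict[str, tuple]) -> None:
    """Raise if the named volumes do not share one grid, reporting shapes."""
    shapes = set(named_shapes.values())
    if len(shapes) > 1:
        detail = ", ".join(f"{k}: {v}" for k, v in named_shapes.items())
        raise ValueError(f"volumes are not on one grid ({detail})")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
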