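"""Reading, slice selection and intensity normalization of subject volumes.

A subject volume is treated as a raw stack of 2D slices along the first
stored axis (the sagittal axis for the clinical acquisitions this mirrors);
NIfTI orientation metadata is deliberately ignored.  From a raw stack of N
slices a centered contiguous window of ``n_keep`` slices (88 by default) is
retained — the end slices of a structural scan carry little anatomy — and
intensities are min–max rescaled to [0, 1] per volume, preserving the
inter-slice contrast that the downstream energy feature encodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "SubjectVolume",
    "read_volume",
    "select_slices",
    "normalize",
    "load_subject",
    "N_KEEP_DEFAULT",
]

N_KEEP_DEFAULT = 88


@dataclass
class SubjectVolume:
    """One subject's stack of selected, normalized slices.

    ``data`` has shape ``(n_slices, H, W)``; ``source_shape`` records the
    shape of the raw file before slice selection.
    """

    subject_id: str
    data: np.ndarray
    label: int | None = None
    source_shape: tuple[int, ...] | None = None

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[int, ...]]:
    """Load a 3D NIfTI file as a float array in (slice, row, col) order.

    The first stored axis is taken as the slice axis; no reorientation is
    applied.  Returns the array and its shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D with shape {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        raise ValueError(f"volume contains {n_nan} NaN voxel(s): {path}")
    return data, tuple(data.shape)


def select_slices(
    raw: np.ndarray, n_keep: int = N_KEEP_DEFAULT, start: int | None = None
) -> np.ndarray:
    """Retain a contiguous window of ``n_keep`` slices.

    By default the window is centered: ``start = floor((N - n_keep) / 2)``,
    discarding equal numbers of low-information end slices.  Order is
    preserved and selecting from an already-selected stack is the identity.
    """
    n = raw.shape[0]
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n < n_keep:
        raise ValueError(f"volume has {n} slices, fewer than n_keep={n_keep}")
    if start is None:
        start = (n - n_keep) // 2
    if start < 0 or start + n_keep > n:
        raise ValueError(f"window [{start}, {start + n_keep}) out of range for {n} slices")
    return raw[start : start + n_keep]


def normalize(volume: np.ndarray) -> np.ndarray:
    """Affine min–max rescaling of the whole volume to [0, 1].

    A constant volume maps to all zeros.  Idempotent, and invariant to
    positive affine rescaling of the input.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    lo = volume.min()
    span = volume.max() - lo
    if span == 0:
        return np.zeros_like(volume)
    return (volume - lo) / span


def load_subject(
    path: str | Path,
    subject_id: str | None = None,
    label: int | None = None,
    n_keep: int = N_KEEP_DEFAULT,
    window_start: int | None = None,
) -> SubjectVolume:
    """read → select centered window → normalize, as one step."""
    raw, source_shape = read_volume(path)
    data = normalize(select_slices(raw, n_keep=n_keep, start=window_start))
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return SubjectVolume(subject_id=subject_id, data=data, label=label, source_shape=source_shape)
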