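"""Subband-specific feature extraction for the three classification routes.

* 1D route: per-slice *energy* of the CD (diagonal detail) subband — the sum
  over pixels of the gradient magnitude — giving one length-``n_slices``
  vector per subject.  Lower edge contrast in a volume lowers its energies.
* 2D route: pixel-wise *mean fusion* of the subject's CH subband stack into
  a single image.
* 3D route: the CV subband stack itself, used as a volume.

The gradient operator is central differences with one-sided differences at
the borders (the minimal stencil that looks at neighbouring pixels); a Sobel
operator is selectable and changes only the scale of the energies, not the
ordering between classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "EnergyVector",
    "FusedImage",
    "gradient_magnitude",
    "slice_energy",
    "energy_vector",
    "mean_fusion",
]


@dataclass
class EnergyVector:
    """Per-subject energy profile: one non-negative value per retained slice."""

    values: np.ndarray
    subject_id: str | None = None
    label: int | None = None

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FusedImage:
    """Pixel-wise mean of a subject's subband stack."""

    data: np.ndarray
    subject_id: str | None = None
    label: int | None = None


def gradient_magnitude(image: np.ndarray, operator: str = "central") -> np.ndarray:
    """Pointwise gradient magnitude sqrt(Gx^2 + Gy^2) of a 2D image.

    ``central`` uses central differences in the interior and one-sided
    differences at the borders; ``sobel`` uses the 3x3 Sobel stencil.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError(f"expected a 2D image with both sides >= 2, got shape {image.shape}")
    if operator == "central":
        gy, gx = np.gradient(image)
    elif operator == "sobel":
        gy = ndimage.sobel(image, axis=0, mode="nearest")
        gx = ndimage.sobel(image, axis=1, mode="nearest")
    else:
        raise ValueError(f"operator must be 'central' or 'sobel', got {operator!r}")
    return np.hypot(gx, gy)


def slice_energy(cd_slice: np.ndarray, operator: str = "central") -> float:
    """Energy of one subband slice: the sum of its gradient magnitudes.

    Positively homogeneous: ``slice_energy(c * X) == c * slice_energy(X)``
    for c > 0; zero iff the slice is constant.
    """
    return float(gradient_magnitude(cd_slice, operator=operator).sum())


def energy_vector(
    cd_volume: np.ndarray,
    subject_id: str | None = None,
    label: int | None = None,
    n_expected: int | None = None,
    operator: str = "central",
) -> EnergyVector:
    """Energy profile of a subject's CD subband stack (one entry per slice).

    ``n_expected`` enforces the configured slice count (88 in the reference
    protocol) when given.
    """
    cd_volume = np.asarray(cd_volume, dtype=np.float64)
    if cd_volume.ndim != 3:
        raise ValueError(f"expected (n_slices, H, W), got shape {cd_volume.shape}")
    if n_expected is not None and cd_volume.shape[0] != n_expected:
        raise ValueError(f"expected {n_expected} slices, got {cd_volume.shape[0]}")
    values = np.array([slice_energy(sl, operator=operator) for sl in cd_volume])
    return EnergyVector(values=values, subject_id=subject_id, label=label)


def mean_fusion(
    ch_volume: np.ndarray, subject_id: str | None = None, label: int | None = None
) -> FusedImage:
    """Pixel-wise arithmetic mean over the slice axis of a subband stack.

    Invariant to slice order and bounded by the per-pixel min/max of the
    stack.
    """
    ch_volume = np.asarray(ch_volume, dtype=np.float64)
    if ch_volume.ndim != 3 or ch_volume.shape[0] == 0:
        raise ValueError(f"expected a non-empty (n_slices, H, W) stack, got shape {ch_volume.shape}")
    return FusedImage(data=ch_volume.mean(axis=0), subject_id=subject_id, label=label)
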