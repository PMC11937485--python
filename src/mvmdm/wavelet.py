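"""Single-level 2D wavelet decomposition of slices and a frequency-domain
ablation filter.

The working wavelet is db1 (Haar): orthonormal 2-tap filters, so each of the
four subbands — CA (approximation), CH (horizontal detail), CV (vertical
detail), CD (diagonal detail) — is exactly half the linear size of an
even-sized slice and the squared coefficients conserve the input's energy
(Parseval).  Periodization boundary handling keeps the ``ceil(n/2)`` subband
shape and the energy accounting for odd sizes too.

Orientation convention: CH carries variation *across rows* (horizontal-edge
content, lowpass along rows / highpass along columns of the index grid), CV
variation across columns.  The 2x2 block ``[[1, 2], [3, 4]]`` maps to
CA = 5, CH = -2, CV = -1, CD = 0 under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "SubbandSet",
    "SubbandVolumes",
    "SUBBAND_NAMES",
    "haar_dwt2",
    "haar_idwt2",
    "dwt2_subbands",
    "idwt2_subbands",
    "decompose_volume",
    "frequency_filter",
    "nyquist_radius",
    "ALLOWED_WAVELETS",
]

SUBBAND_NAMES = ("CA", "CH", "CV", "CD")
# db1 is the working wavelet; the others are accepted for subband/wavelet
# ablation protocols.
ALLOWED_WAVELETS = ("db1", "db2", "sym2", "coif1")
_MODE = "periodization"


@dataclass
class SubbandSet:
    """The four coefficient images of one slice, each ceil(H/2) x ceil(W/2)."""

    CA: np.ndarray
    CH: np.ndarray
    CV: np.ndarray
    CD: np.ndarray

    def get(self, name: str) -> np.ndarray:
        if name not in SUBBAND_NAMES:
            raise KeyError(f"unknown subband {name!r}; expected one of {SUBBAND_NAMES}")
        return getattr(self, name)


@dataclass
class SubbandVolumes:
    """Per-slice subband stacks for one subject: four (n_slices, H/2, W/2) arrays."""

    CA: np.ndarray
    CH: np.ndarray
    CV: np.ndarray
    CD: np.ndarray

    def get(self, name: str) -> np.ndarray:
        if name not in SUBBAND_NAMES:
            raise KeyError(f"unknown subband {name!r}; expected one of {SUBBAND_NAMES}")
        return getattr(self, name)

    @property
    def n_slices(self) -> int:
        return self.CA.shape[0]


def _check_wavelet(wavelet: str) -> None:
    if wavelet not in ALLOWED_WAVELETS:
        raise ValueError(f"wavelet must be one of {ALLOWED_WAVELETS}, got {wavelet!r}")


def dwt2_subbands(image: np.ndarray, wavelet: str = "db1") -> SubbandSet:
    """One analysis level of the separable 2D DWT of a single slice."""
    _check_wavelet(wavelet)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError(f"expected a 2D image with both sides >= 2, got shape {image.shape}")
    ca, (ch, cv, cd) = pywt.dwt2(image, wavelet, mode=_MODE)
    return SubbandSet(CA=ca, CH=ch, CV=cv, CD=cd)


def idwt2_subbands(subbands: SubbandSet, wavelet: str = "db1") -> np.ndarray:
    """Inverse of :func:`dwt2_subbands`; exact reconstruction for even sizes."""
    _check_wavelet(wavelet)
    shapes = {s.shape for s in (subbands.CA, subbands.CH, subbands.CV, subbands.CD)}
    if len(shapes) != 1:
        raise ValueError(f"subband shapes differ: {sorted(shapes)}")
    return pywt.idwt2((subbands.CA, (subbands.CH, subbands.CV, subbands.CD)), wavelet, mode=_MODE)


def haar_dwt2(image: np.ndarray) -> SubbandSet:
    """Single-level orthonormal Haar (db1) decomposition of one slice."""
    return dwt2_subbands(image, "db1")


def haar_idwt2(subbands: SubbandSet) -> np.ndarray:
    """Perfect-reconstruction inverse of :func:`haar_dwt2`."""
    return idwt2_subbands(subbands, "db1")


def decompose_volume(volume, wavelet: str = "db1") -> SubbandVolumes:
    """Slice-wise decomposition of a subject volume; no cross-slice mixing.

    Accepts a :class:`~mvmdm.volume_io.SubjectVolume` or a plain 3D array of
    shape (n_slices, H, W) and returns four (n_slices, ceil(H/2), ceil(W/2))
    stacks.
    """
    data = getattr(volume, "data", volume)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected (n_slices, H, W), got shape {data.shape}")
    per_slice = [dwt2_subbands(sl, wavelet) for sl in data]
    return SubbandVolumes(
        CA=np.stack([s.CA for s in per_slice]),
        CH=np.stack([s.CH for s in per_slice]),
        CV=np.stack([s.CV for s in per_slice]),
        CD=np.stack([s.CD for s in per_slice]),
    )


def nyquist_radius(shape: tuple[int, int]) -> float:
    """Largest radial spatial frequency (cycles per image) on the FFT grid.

    Attained at the corner of the half-spectrum; a lowpass at this cutoff
    passes every representable frequency.
    """
    h, w = shape
    return float(np.hypot(h // 2, w // 2))


def frequency_filter(image: np.ndarray, cutoff: float, mode: str) -> np.ndarray:
    """Ideal radial lowpass/highpass filter in the 2D Fourier domain.

    Frequencies are measured in cycles per image.  ``lowpass`` keeps radii
    <= cutoff; ``highpass`` keeps radii > cutoff (the DC component is always
    removed).  The output is real-valued with the input's shape.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    if mode not in ("lowpass", "highpass"):
        raise ValueError(f"mode must be 'lowpass' or 'highpass', got {mode!r}")
    nyq = nyquist_radius(image.shape)
    if not 0 < cutoff <= nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq:.3f}] cycles/image, got {cutoff}")
    h, w = image.shape
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    radius = np.hypot(fy[:, None], fx[None, :])
    if mode == "lowpass":
        mask = radius <= cutoff
    else:
        mask = radius > cutoff
    spectrum = np.fft.fft2(image) * mask
    return np.real(np.fft.ifft2(spectrum))
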