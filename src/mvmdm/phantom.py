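"""Synthetic phantom cohorts with class-dependent gradient-magnitude energy.

The generator emulates the statistical structure the classification pipeline
relies on: stacks of sagittal-like slices containing smooth "tissue"
structures whose edge contrast is reduced in the disease class (label 1), so
that the per-slice sum of gradient magnitudes — the energy feature — is
systematically lower for that class while everything else about the two
classes is exchangeable.

Phantom content
---------------
Each volume is a dark background plus, when ``n_blobs > 0``, a fixed-contrast
circular rim (a crude skull) and ``n_blobs`` ellipsoidal blobs with thin
linear intensity ramps at their boundaries.  Energy is a sum of gradient
magnitudes, so it is dominated by those ramps; scaling the blob amplitude of
class-1 subjects by ``(1 - effect)`` scales their edge contrast and hence
their energy, monotonically in ``effect``.  The rim is never scaled: it
anchors the intensity range of every volume so that per-volume min–max
normalization downstream does not cancel the class contrast.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "PhantomConfig",
    "CohortManifest",
    "ManifestRecord",
    "generate_subject",
    "generate_cohort",
    "load_manifest",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom generator.

    Parameters
    ----------
    n_slices
        Slices per subject volume.  88 matches the retained window of the
        clinical protocol this generator emulates.
    slice_size
        Pixels per slice side; must be even so one wavelet level yields
        exact half-size subbands.
    effect
        Relative reduction of blob edge contrast in class 1, in [0, 1].
        0 makes the two classes exchangeable.
    noise_sd
        Standard deviation of additive Gaussian voxel noise, on the [0, 1]
        intensity scale (0.02 corresponds to a high-SNR structural scan).
    n_blobs
        Number of ellipsoidal structures per volume.
    seed
        Default cohort seed used by :func:`generate_cohort` when none is
        passed explicitly.
    """

    n_slices: int = 88
    slice_size: int = 256
    effect: float = 0.6
    noise_sd: float = 0.02
    n_blobs: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.slice_size < 2 or self.slice_size % 2 != 0:
            raise ValueError(
                f"slice_size must be even (got {self.slice_size}): one wavelet "
                "level halves each slice dimension exactly only for even sizes"
            )
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")


@dataclass(frozen=True)
class ManifestRecord:
    subject_id: str
    path: str
    label: int
    dataset: str


@dataclass
class CohortManifest:
    """Table of subjects: id, file path, binary label, dataset tag."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        for r in self.records:
            if r.label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {r.label!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "path", "label", "dataset"])
            for r in self.records:
                w.writerow([r.subject_id, r.path, r.label, r.dataset])


def load_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV and check that every volume path resolves."""
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"subject_id", "path", "label", "dataset"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise ValueError(f"manifest must have columns {sorted(expected)}")
        for row in reader:
            p = Path(row["path"])
            if not p.is_absolute():
                p = path.parent / p
            if not p.exists():
                raise FileNotFoundError(f"volume not found: {p}")
            records.append(
                ManifestRecord(row["subject_id"], str(p), int(row["label"]), row["dataset"])
            )
    return CohortManifest(records)


def _ellipsoid_field(
    shape: tuple[int, int, int],
    center: np.ndarray,
    axes: np.ndarray,
    amplitude: float,
    edge_width: float = 0.3,
) -> np.ndarray:
    """Ellipsoid with a thin linear intensity ramp at its boundary.

    Intensity is ``amplitude * clip((1 - q) / edge_width, 0, 1)`` where
    ``q`` is the ellipsoid quadratic form; the ramp occupies the shell
    ``1 - edge_width <= q <= 1`` so the gradient (and hence the energy this
    blob contributes) is concentrated at the edge and scales linearly with
    ``amplitude``.
    """
    zz = (np.arange(shape[0])[:, None, None] - center[0]) / axes[0]
    yy = (np.arange(shape[1])[None, :, None] - center[1]) / axes[1]
    xx = (np.arange(shape[2])[None, None, :] - center[2]) / axes[2]
    q = zz * zz + yy * yy + xx * xx
    return amplitude * np.clip((1.0 - q) / edge_width, 0.0, 1.0)


def _rim(shape: tuple[int, int, int]) -> np.ndarray:
    """Fixed-contrast circular rim, identical on every slice and for every
    subject; anchors the volume's intensity range."""
    n, h, w = shape
    r0 = 0.45 * min(h, w)
    yy = np.arange(h)[:, None] - (h - 1) / 2.0
    xx = np.arange(w)[None, :] - (w - 1) / 2.0
    r = np.hypot(yy, xx)
    ring = 0.9 * np.exp(-((r - r0) / 1.5) ** 2)
    return np.broadcast_to(ring, (n, h, w)).copy()


def _blob_template(cfg: PhantomConfig) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Shared "anatomy": blob centers, semi-axes and base amplitudes.

    Determined by the phantom geometry alone, so every subject generated
    under one configuration carries the same underlying structures (as real
    subjects share anatomy) and mean-fused images remain structured.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([424242, cfg.n_blobs, cfg.n_slices, cfg.slice_size])
    )
    n, s = cfg.n_slices, cfg.slice_size
    template = []
    for _ in range(cfg.n_blobs):
        center = np.array(
            [
                rng.uniform(0.2 * n, 0.8 * n),
                rng.uniform(0.25 * s, 0.75 * s),
                rng.uniform(0.25 * s, 0.75 * s),
            ]
        )
        axes = np.array(
            [
                rng.uniform(0.10, 0.35) * n,
                rng.uniform(0.06, 0.18) * s,
                rng.uniform(0.06, 0.18) * s,
            ]
        )
        template.append((center, axes, float(rng.uniform(0.3, 0.8))))
    return template


def generate_subject(label: int, cfg: PhantomConfig, subject_seed: int) -> np.ndarray:
    """Generate one phantom volume of shape ``(n_slices, slice_size, slice_size)``.

    Values are finite and lie in [0, 1].  Two calls with identical arguments
    return identical volumes.  For label 1 the expected slice energy is
    strictly decreasing in ``cfg.effect``.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    shape = (cfg.n_slices, cfg.slice_size, cfg.slice_size)
    # The seed alone fixes the blob draws: two subjects differing only in
    # label share geometry, so the label acts purely through edge contrast.
    rng = np.random.default_rng(np.random.SeedSequence([int(subject_seed) & 0x7FFFFFFF]))

    if cfg.n_blobs == 0 and cfg.noise_sd == 0:
        return np.zeros(shape, dtype=np.float32) + np.float32(0.05)

    vol = np.full(shape, 0.05, dtype=np.float64)
    if cfg.n_blobs > 0:
        vol += _rim(shape)
        n, s = cfg.n_slices, cfg.slice_size
        gain = rng.uniform(0.85, 1.15)  # per-subject intensity variation
        contrast = (1.0 - cfg.effect) if label == 1 else 1.0
        for center, axes, amp in _blob_template(cfg):
            # Subjects share the template "anatomy"; each jitters position,
            # size and brightness slightly, the way real anatomy varies.
            jitter = rng.normal(0.0, 0.02, size=3) * np.array([n, s, s])
            sz = rng.uniform(0.9, 1.1, size=3)
            vol += _ellipsoid_field(
                shape,
                center + jitter,
                axes * sz,
                amp * rng.uniform(0.9, 1.1) * gain * contrast,
            )
    if cfg.noise_sd > 0:
        vol += rng.normal(0.0, cfg.noise_sd, size=shape)
    np.clip(vol, 0.0, 1.0, out=vol)
    return vol.astype(np.float32)


def subject_seed_for(cohort_seed: int, index: int) -> int:
    """Deterministic per-subject seed, independent across subject indices."""
    ss = np.random.SeedSequence([int(cohort_seed) & 0x7FFFFFFF, int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_cohort(
    n_per_class: int,
    cfg: PhantomConfig,
    out_dir: str | Path,
    seed: int | None = None,
    dataset_tag: str = "phantom",
) -> CohortManifest:
    """Write ``2 * n_per_class`` phantom volumes as NIfTI plus a manifest CSV.

    Labels alternate (0, 1, 0, 1, ...), volumes carry an identity affine,
    and the whole cohort is reproducible from ``(cfg, seed)``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seed = cfg.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for idx in range(2 * n_per_class):
        label = idx % 2
        sid = f"{dataset_tag}_{'sz' if label else 'hc'}_{idx:04d}"
        vol = generate_subject(label, cfg, subject_seed_for(seed, idx))
        path = out_dir / f"{sid}.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
        records.append(ManifestRecord(sid, str(path), label, dataset_tag))
    manifest = CohortManifest(records)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def generate_cohort_arrays(
    n_per_class: int, cfg: PhantomConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """In-memory variant of :func:`generate_cohort`: (volumes, labels, ids).

    Uses the same per-subject seeds as the on-disk writer, so the two agree
    voxel for voxel.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seed = cfg.seed if seed is None else seed
    vols, labels, ids = [], [], []
    for idx in range(2 * n_per_class):
        label = idx % 2
        vols.append(generate_subject(label, cfg, subject_seed_for(seed, idx)))
        labels.append(label)
        ids.append(f"mem_{'sz' if label else 'hc'}_{idx:04d}")
    return np.stack(vols), np.array(labels, dtype=int), ids
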