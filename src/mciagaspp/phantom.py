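"""Synthetic gray-matter phantoms with localized atrophy.

Real MCI cohorts (access-restricted clinical MRI) are emulated by a
parametric phantom: a smooth anatomical background built from fixed
anisotropic Gaussian bumps, a per-subject multiplicative gain shared by
all of a subject's longitudinal scans, small ellipsoidal lesion regions
whose intensity is multiplied by an atrophy factor for the impaired
class, and i.i.d. Gaussian voxel noise.  Intensities are clamped to
[0, 1] like tissue-probability maps.

All randomness derives from independent substreams hashed from
(seed, subject_id, scan_index), so cohorts are reproducible and can be
extended without disturbing existing volumes.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import Cohort, Volume, write_manifest, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "background_template"]

FULL_GRID = (84, 102, 84)
SMALL_GRID = (32, 40, 32)

# (center fractions, axis sigma fractions, amplitude) of the fixed
# background bumps; the two narrow off-center bumps sit at the lesion
# loci so lesions land on substantial gray-matter signal, mimicking
# hippocampus-adjacent structures.
_BACKGROUND_BUMPS = [
    ((0.50, 0.50, 0.50), (0.32, 0.34, 0.32), 0.55),
    ((0.30, 0.35, 0.35), (0.12, 0.12, 0.12), 0.35),
    ((0.70, 0.35, 0.35), (0.12, 0.12, 0.12), 0.35),
    ((0.50, 0.72, 0.50), (0.16, 0.14, 0.16), 0.30),
    ((0.32, 0.60, 0.62), (0.10, 0.11, 0.10), 0.22),
    ((0.68, 0.60, 0.62), (0.10, 0.11, 0.10), 0.22),
]

_LESION_CENTER_FRACTIONS = [(0.30, 0.35, 0.35), (0.70, 0.35, 0.35)]
_LESION_RADIUS_FRACTION = 0.06


def _default_lesions(grid_shape):
    centers = [
        tuple(int(round(f * (n - 1))) for f, n in zip(fracs, grid_shape))
        for fracs in _LESION_CENTER_FRACTIONS
    ]
    radii = tuple(max(2, int(round(_LESION_RADIUS_FRACTION * n))) for n in grid_shape)
    return centers, radii


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a synthetic cohort.

    atrophy_factor multiplies lesion-interior intensity for class-1
    (MCI-like) volumes; 1.0 makes the classes indistinguishable.
    subject_effect_sd is the sd of the per-subject multiplicative gain
    (1 + N(0, sd)), shared across a subject's scans; noise_sd is the sd
    of the additive per-voxel noise.
    """

    grid_shape: tuple[int, int, int] = SMALL_GRID
    n_subjects_per_class: int = 40
    scans_per_subject: int = 1
    lesion_centers: list[tuple[int, int, int]] | None = None
    lesion_radii: tuple[float, float, float] | None = None
    atrophy_factor: float = 0.6
    noise_sd: float = 0.05
    subject_effect_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 4 for n in self.grid_shape):
            raise ValueError(f"invalid grid_shape {self.grid_shape}")
        if self.lesion_centers is None or self.lesion_radii is None:
            centers, radii = _default_lesions(self.grid_shape)
            if self.lesion_centers is None:
                self.lesion_centers = centers
            if self.lesion_radii is None:
                self.lesion_radii = radii
        self.lesion_centers = [tuple(float(c) for c in ctr) for ctr in self.lesion_centers]
        self.lesion_radii = tuple(float(r) for r in self.lesion_radii)
        if not 0.0 < self.atrophy_factor <= 1.0:
            raise ValueError("atrophy_factor must be in (0, 1]")
        if self.noise_sd < 0 or self.subject_effect_sd < 0:
            raise ValueError("noise_sd and subject_effect_sd must be >= 0")
        if self.scans_per_subject < 1 or self.n_subjects_per_class < 1:
            raise ValueError("counts must be >= 1")
        for ctr in self.lesion_centers:
            for c, r, n in zip(ctr, self.lesion_radii, self.grid_shape):
                if c - r < 0 or c + r > n - 1:
                    raise ValueError(
                        f"lesion at {ctr} with radii {self.lesion_radii} exceeds grid "
                        f"{self.grid_shape}"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["lesion_centers"] = [list(c) for c in self.lesion_centers]
        d["lesion_radii"] = list(self.lesion_radii)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)


def background_template(grid_shape) -> np.ndarray:
    """Deterministic smooth background: superposition of fixed Gaussian bumps."""
    grid_shape = tuple(int(n) for n in grid_shape)
    axes = [np.linspace(0.0, 1.0, n) for n in grid_shape]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    acc = np.zeros(grid_shape)
    for (cz, cy, cx), (sz, sy, sx), amp in _BACKGROUND_BUMPS:
        acc += amp * np.exp(
            -0.5 * (((Z - cz) / sz) ** 2 + ((Y - cy) / sy) ** 2 + ((X - cx) / sx) ** 2)
        )
    return np.clip(acc, 0.0, 0.95)


def lesion_mask(spec: PhantomSpec) -> np.ndarray:
    """Union of the spec's lesion ellipsoids as a boolean volume."""
    axes = [np.arange(n, dtype=float) for n in spec.grid_shape]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    rz, ry, rx = spec.lesion_radii
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for cz, cy, cx in spec.lesion_centers:
        mask |= ((Z - cz) / rz) ** 2 + ((Y - cy) / ry) ** 2 + ((X - cx) / rx) ** 2 <= 1.0
    return mask


def _substream(seed: int, *tokens) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF]
    for tok in tokens:
        h = hashlib.sha256(str(tok).encode()).digest()
        entropy.append(int.from_bytes(h[:4], "little"))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def subject_gain(spec: PhantomSpec, subject_id: str) -> float:
    """Per-subject multiplicative gain, identical across that subject's scans."""
    rng = _substream(spec.seed, "subject", subject_id)
    return float(1.0 + rng.normal(0.0, spec.subject_effect_sd)) if spec.subject_effect_sd > 0 else 1.0


def generate_phantom(
    spec: PhantomSpec, subject_id: str, scan_index: int, label: int
) -> Volume:
    """Render one phantom scan; fully deterministic given (seed, ids)."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    mask = lesion_mask(spec)
    voxels = background_template(spec.grid_shape).copy()
    if label == 1:
        voxels[mask] *= spec.atrophy_factor
    voxels *= subject_gain(spec, subject_id)
    if spec.noise_sd > 0:
        rng = _substream(spec.seed, "noise", subject_id, scan_index)
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    voxels = np.clip(voxels, 0.0, 1.0).astype(np.float32)
    return Volume(
        voxels=voxels,
        subject_id=subject_id,
        scan_id=f"{subject_id}_t{scan_index:02d}",
        label=label,
        lesion_mask=mask,
    )


def generate_cohort(spec: PhantomSpec, out_dir) -> Cohort:
    """Write a full two-class cohort (NIfTI volumes + TSV manifest).

    Produces n_subjects_per_class x 2 subjects, each with
    scans_per_subject longitudinal scans sharing the subject gain.
    Returns the cohort; the manifest lands at ``<out_dir>/manifest.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, prefix in ((0, "nc"), (1, "mci")):
        for s in range(spec.n_subjects_per_class):
            subject_id = f"{prefix}{s:03d}"
            for t in range(spec.scans_per_subject):
                vol = generate_phantom(spec, subject_id, t, label)
                path = out_dir / f"{vol.scan_id}.nii"
                write_volume(vol, path)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "scan_id": vol.scan_id,
                        "label": label,
                        "path": str(path),
                    }
                )
    cohort = Cohort(pd.DataFrame(rows), spec.grid_shape)
    write_manifest(cohort, out_dir / "manifest.tsv")
    return cohort
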