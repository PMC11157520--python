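"""Deterministic 25x training-data augmentation.

The catalogue combines the three stock families for volumetric data —
axis flips, small rigid rotations, and additive Gaussian noise — into a
fixed, ordered list of 25 transforms whose first entry is the identity,
so one input volume expands to 25 training volumes:

    1 identity + 3 single-axis flips
      + 12 rotations (+/-5 and +/-10 degrees about each axis)
      + 9 noise variants (sd in {0.01, 0.02, 0.03} x 3 seeded draws).

Noise draws are seeded per (catalogue seed, entry, scan), so the
expansion of a given volume is reproducible.  Augmentation is meant for
the training side only, after the subject-level split.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_io import Cohort, Volume, write_manifest, write_volume

__all__ = [
    "Transform",
    "AugmentCatalogue",
    "default_catalogue",
    "augment_volume",
    "expansion_factor",
    "augment_cohort",
]

_ROTATION_PLANES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


@dataclasses.dataclass(frozen=True)
class Transform:
    """One catalogue entry.

    kind: 'identity' | 'flip' | 'rotate' | 'noise'.
    axis: flip axis or rotation axis; angle in degrees; noise_sd the
    additive noise scale; draw distinguishes repeated noise entries.
    """

    kind: str
    axis: int | None = None
    angle: float | None = None
    noise_sd: float | None = None
    draw: int | None = None

    def describe(self) -> str:
        if self.kind == "identity":
            return "identity"
        if self.kind == "flip":
            return f"flip(axis={self.axis})"
        if self.kind == "rotate":
            return f"rotate(axis={self.axis}, angle={self.angle:+g})"
        return f"noise(sd={self.noise_sd}, draw={self.draw})"


@dataclasses.dataclass
class AugmentCatalogue:
    transforms: list[Transform]
    seed: int = 0

    def __post_init__(self):
        if not self.transforms or self.transforms[0].kind != "identity":
            raise ValueError("catalogue must start with the identity transform")

    def __len__(self) -> int:
        return len(self.transforms)


def default_catalogue(
    seed: int = 0,
    rotation_angles: tuple[float, ...] = (5.0, -5.0, 10.0, -10.0),
    noise_sds: tuple[float, ...] = (0.01, 0.02, 0.03),
    noise_draws: int = 3,
) -> AugmentCatalogue:
    """The standard 25-entry catalogue (1 + 3 + 12 + 9)."""
    transforms = [Transform("identity")]
    transforms += [Transform("flip", axis=ax) for ax in range(3)]
    transforms += [
        Transform("rotate", axis=ax, angle=ang)
        for ax in range(3)
        for ang in rotation_angles
    ]
    transforms += [
        Transform("noise", noise_sd=sd, draw=d)
        for sd in noise_sds
        for d in range(noise_draws)
    ]
    return AugmentCatalogue(transforms, seed=seed)


def expansion_factor(cat: AugmentCatalogue) -> int:
    """Number of output volumes produced per input volume."""
    return len(cat.transforms)


def _noise_rng(cat: AugmentCatalogue, entry: int, volume: Volume) -> np.random.Generator:
    h = hashlib.sha256(f"{volume.subject_id}|{volume.scan_id}".encode()).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(cat.seed) & 0x7FFFFFFF, entry, int.from_bytes(h[:4], "little")])
    )


def apply_transform(volume: Volume, t: Transform, rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply one transform to the voxel array (and lesion mask, if any)."""
    vox = volume.voxels
    mask = volume.lesion_mask
    if t.kind == "identity":
        return vox.copy(), None if mask is None else mask.copy()
    if t.kind == "flip":
        return np.flip(vox, axis=t.axis).copy(), None if mask is None else np.flip(mask, axis=t.axis).copy()
    if t.kind == "rotate":
        plane = _ROTATION_PLANES[t.axis]
        out = ndimage.rotate(
            vox, t.angle, axes=plane, reshape=False, order=1, mode="constant", cval=0.0
        )
        m = None
        if mask is not None:
            m = ndimage.rotate(
                mask.astype(np.float32), t.angle, axes=plane, reshape=False,
                order=0, mode="constant", cval=0.0,
            ) > 0.5
        return out.astype(vox.dtype, copy=False), m
    if t.kind == "noise":
        if rng is None:
            raise ValueError("noise transform needs a random generator")
        noisy = vox + rng.normal(0.0, t.noise_sd, size=vox.shape).astype(vox.dtype)
        return noisy, None if mask is None else mask.copy()
    raise ValueError(f"unknown transform kind {t.kind!r}")


def augment_volume(volume: Volume, cat: AugmentCatalogue) -> list[Volume]:
    """Expand one volume through the whole catalogue.

    Entry 0 reproduces the input exactly; every output keeps the input's
    subject_id, label and grid shape, with the scan_id suffixed by the
    catalogue entry index.
    """
    if volume.voxels.ndim != 3:
        raise ValueError("augment_volume expects a rank-3 voxel array")
    out = []
    for i, t in enumerate(cat.transforms):
        rng = _noise_rng(cat, i, volume) if t.kind == "noise" else None
        vox, mask = apply_transform(volume, t, rng)
        scan_id = volume.scan_id if i == 0 else f"{volume.scan_id}.aug{i:02d}"
        out.append(
            Volume(
                voxels=vox,
                subject_id=volume.subject_id,
                scan_id=scan_id,
                label=volume.label,
                spacing=volume.spacing,
                lesion_mask=mask,
            )
        )
    return out


def augment_cohort(cohort: Cohort, cat: AugmentCatalogue, out_dir) -> Cohort:
    """Expand every scan of a cohort to disk; returns the expanded cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, row in cohort.records.iterrows():
        from .data_io import read_volume

        vol = read_volume(row["path"], row, grid_shape=cohort.grid_shape)
        for av in augment_volume(vol, cat):
            path = out_dir / f"{av.scan_id}.nii"
            write_volume(av, path)
            rows.append(
                {
                    "subject_id": av.subject_id,
                    "scan_id": av.scan_id,
                    "label": av.label,
                    "path": str(path),
                }
            )
    expanded = Cohort(pd.DataFrame(rows), cohort.grid_shape)
    write_manifest(expanded, out_dir / "manifest.tsv")
    return expanded
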