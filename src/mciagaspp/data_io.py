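"""Volume and cohort I/O plus leakage-free subject-level splitting.

Volumes are NIfTI-1 images used in stored index order (inputs are
assumed spatially normalized upstream, so no reorientation is applied).
A cohort manifest is a TSV with columns ``subject_id  scan_id  label
path``, one row per scan; the subject is the unit of splitting so that
longitudinal scans of one person never straddle train and test.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "Cohort",
    "read_volume",
    "write_volume",
    "read_manifest",
    "write_manifest",
    "subject_split",
]

MANIFEST_COLUMNS = ["subject_id", "scan_id", "label", "path"]


@dataclasses.dataclass
class Volume:
    """A 3D scalar field with scan metadata.

    label: 0 = normal control (NC), 1 = mild cognitive impairment (MCI).
    lesion_mask is only available for synthetic phantoms, where ground
    truth lesion geometry is known.
    """

    voxels: np.ndarray
    subject_id: str
    scan_id: str
    label: int
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    lesion_mask: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be rank 3, got shape {self.voxels.shape}")
        if int(self.label) not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        self.label = int(self.label)
        if self.lesion_mask is not None:
            self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
            if self.lesion_mask.shape != self.voxels.shape:
                raise ValueError("lesion_mask shape differs from voxels shape")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)


@dataclasses.dataclass
class Cohort:
    """Manifest of scans grouped by subject."""

    records: pd.DataFrame
    grid_shape: tuple[int, int, int]

    def __post_init__(self):
        df = pd.DataFrame(self.records).reset_index(drop=True)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        df = df[MANIFEST_COLUMNS].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["scan_id"] = df["scan_id"].astype(str)
        df["label"] = df["label"].astype(int)
        df["path"] = df["path"].astype(str)
        if not df["label"].isin([0, 1]).all():
            raise ValueError("labels must be 0 or 1")
        if df["path"].duplicated().any():
            dupes = df.loc[df["path"].duplicated(), "path"].tolist()
            raise ValueError(f"duplicate scan paths in manifest: {dupes[:3]}")
        per_subject = df.groupby("subject_id")["label"].nunique()
        conflicted = per_subject[per_subject > 1].index.tolist()
        if conflicted:
            raise ValueError(f"subjects with conflicting labels: {conflicted}")
        self.records = df
        self.grid_shape = tuple(int(v) for v in self.grid_shape)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.records["subject_id"].unique())

    def subject_labels(self) -> pd.Series:
        return self.records.groupby("subject_id")["label"].first()

    def subset_by_subjects(self, subject_ids) -> "Cohort":
        keep = self.records["subject_id"].isin(set(subject_ids))
        return Cohort(self.records[keep], self.grid_shape)

    def load_volumes(self) -> list[Volume]:
        return [read_volume(row["path"], row, grid_shape=self.grid_shape)
                for _, row in self.records.iterrows()]


def write_volume(volume: Volume, path: str | os.PathLike) -> Path:
    """Write a volume as NIfTI-1 with a diagonal affine from its spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def read_volume(path: str | os.PathLike, manifest_row, grid_shape=None) -> Volume:
    """Load a NIfTI volume with metadata taken from its manifest row.

    The stored array is returned in index order, no reorientation.
    Raises FileNotFoundError for a missing file and ValueError when the
    on-disk shape disagrees with the manifest grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj)
    if voxels.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {voxels.shape}")
    if grid_shape is not None and tuple(voxels.shape) != tuple(grid_shape):
        raise ValueError(
            f"{path}: shape {voxels.shape} does not match manifest grid {tuple(grid_shape)}"
        )
    zooms = img.header.get_zooms()[:3]
    return Volume(
        voxels=voxels,
        subject_id=str(manifest_row["subject_id"]),
        scan_id=str(manifest_row["scan_id"]),
        label=int(manifest_row["label"]),
        spacing=tuple(float(z) for z in zooms),
    )


def write_manifest(cohort: Cohort, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.records.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | os.PathLike, grid_shape) -> Cohort:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "scan_id": str})
    return Cohort(df, grid_shape)


def subject_split(
    cohort: Cohort, test_fraction: float, seed: int
) -> tuple[Cohort, Cohort]:
    """Split a cohort by subject into train and test portions.

    Per class the test side receives round(test_fraction * n_subjects)
    subjects (at least one), drawn without replacement from a seeded
    shuffle, and all of their scans.  Train and test subject sets are
    disjoint by construction.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    labels = cohort.subject_labels()
    rng = np.random.default_rng(seed)
    test_subjects: list[str] = []
    for cls in (0, 1):
        subjects = sorted(labels.index[labels == cls])
        if len(subjects) < 2:
            raise ValueError(
                f"class {cls} has {len(subjects)} subject(s); need at least 2 to split"
            )
        n_test = max(1, int(round(test_fraction * len(subjects))))
        if n_test >= len(subjects):
            raise ValueError(
                f"test allocation for class {cls} would take all {len(subjects)} subjects"
            )
        order = rng.permutation(len(subjects))
        test_subjects.extend(subjects[i] for i in order[:n_test])
    train = cohort.subset_by_subjects(set(labels.index) - set(test_subjects))
    test = cohort.subset_by_subjects(test_subjects)
    assert not set(train.subjects) & set(test.subjects), "subject leakage in split"
    return train, test
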