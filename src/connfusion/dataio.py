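"""Reading and writing the formats the pipeline touches.

NIfTI-1 for BOLD volumes and parcellation atlases (via nibabel), CSV for
subject manifests (via pandas), JSON for metric reports.  The pipeline
assumes atlas and functional data already share one voxel grid (MNI-
registered upstream); any geometric mismatch is a hard error, never a
resample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DimensionalityError, GeometryError, ValidationError

#: canonical class names; index 1 is the positive (diagnosed) class
CLASS_NAMES = ("control", "ASD")


@dataclass
class Volume4D:
    """A BOLD scan: real-valued grid with axes (H, W, D, T).

    ``voxel_dims`` is the physical spacing in mm, kept as metadata only.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"Volume4D requires 4 axes (H,W,D,T), got {self.data.ndim}"
            )
        if self.data.shape[3] < 2:
            raise ValidationError("Volume4D requires at least 2 time frames")
        if min(self.data.shape[:3]) < 1:
            raise ValidationError("Volume4D spatial dims must be >= 1")
        bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if bad:
            raise ValidationError(f"Volume4D contains {bad} non-finite voxels")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class ParcellationAtlas:
    """Integer label volume; 0 is background, nonzero labels are regions."""

    labels: np.ndarray
    region_ids: list[int] = field(init=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(
                f"atlas requires 3 axes (H,W,D), got {self.labels.ndim}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded, atol=1e-6):
                raise ValidationError("atlas voxel values are not integer labels")
            self.labels = rounded.astype(np.int32)
        ids = np.unique(self.labels)
        self.region_ids = [int(i) for i in ids if i != 0]
        if len(self.region_ids) < 2:
            raise ValidationError(
                f"atlas must contain >= 2 nonzero labels, found {len(self.region_ids)}"
            )

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass
class SubjectRecord:
    subject_id: str
    volume_path: str
    label: str  # one of CLASS_NAMES


def _affine(voxel_dims):
    aff = np.eye(4)
    if voxel_dims is not None:
        aff[0, 0], aff[1, 1], aff[2, 2] = voxel_dims
    return aff


def write_volume4d(path: str | Path, volume: Volume4D) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data), _affine(volume.voxel_dims))
    nib.save(img, str(path))
    return path


def read_volume4d(path: str | Path) -> Volume4D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 4:
        raise DimensionalityError(
            f"{path}: expected a 4D NIfTI image, got {img.ndim} axes"
        )
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    vol = Volume4D(data=data, voxel_dims=tuple(float(z) for z in zooms))
    return vol


def write_atlas(path: str | Path, atlas: ParcellationAtlas,
                voxel_dims=None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), _affine(voxel_dims))
    nib.save(img, str(path))
    return path


def read_atlas(path: str | Path, expected_grid: tuple[int, int, int]) -> ParcellationAtlas:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D NIfTI label image, got {img.ndim} axes"
        )
    labels = np.asarray(img.dataobj)
    atlas = ParcellationAtlas(labels=labels)
    if tuple(atlas.grid) != tuple(expected_grid):
        raise GeometryError(
            f"{path}: atlas grid {atlas.grid} does not match expected "
            f"{tuple(expected_grid)}"
        )
    return atlas


_LABEL_MAP = {"asd": "ASD", "control": "control"}


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Parse a subject manifest CSV (columns subject_id, volume_path, label)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "volume_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if df.empty:
        return []
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate subject_id values: {sorted(set(dupes))}")
    records = []
    for row in df.itertuples(index=False):
        key = str(row.label).strip().lower()
        if key not in _LABEL_MAP:
            raise ValidationError(
                f"unknown label {row.label!r} for subject {row.subject_id}; "
                f"accepted labels: {sorted(set(_LABEL_MAP.values()))}"
            )
        records.append(SubjectRecord(str(row.subject_id), str(row.volume_path),
                                     _LABEL_MAP[key]))
    return records


def write_manifest(path: str | Path, records: list[SubjectRecord]) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(r.subject_id, r.volume_path, r.label) for r in records],
        columns=["subject_id", "volume_path", "label"],
    ).to_csv(path, index=False)
    return path


def write_metrics_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def labels_to_indices(labels: list[str]) -> np.ndarray:
    """Map class names to integer targets (control -> 0, ASD -> 1)."""
    idx = {name: i for i, name in enumerate(CLASS_NAMES)}
    try:
        return np.array([idx[l] for l in labels], dtype=np.int64)
    except KeyError as e:
        raise ValidationError(f"unknown class label {e.args[0]!r}") from None
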