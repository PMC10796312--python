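"""Volumetric image carrier and NRRD / manifest I/O.

A :class:`PetVolume` stores voxel intensities in SUV units on a regular
grid with physical spacing.  Arrays are indexed ``[x, y, z]`` with z the
axial direction; the physical position of voxel ``(i, j, k)`` is
``origin + index * spacing`` (voxel-centre convention).  NRRD files are
read and written through SimpleITK, which uses the same x-fastest axis
ordering on disk; the in-memory transpose is handled here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

MANIFEST_COLUMNS = ["subject_id", "path", "label", "center_x_mm",
                    "center_y_mm", "center_z_mm", "diameter_mm"]

LABELS = ("benign", "malignant")


@dataclass
class PetVolume:
    """3D grid of non-negative SUV intensities with physical geometry."""

    values: np.ndarray              # indexed [x, y, z]
    spacing_mm: np.ndarray          # per-axis, strictly positive
    origin_mm: np.ndarray = None
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("PetVolume expects a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV intensities must be >= 0")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64)
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be three positive lengths")
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)

    @property
    def shape(self):
        return self.values.shape

    def extent_mm(self):
        """Physical size spanned by voxel centres, per axis."""
        return (np.array(self.shape) - 1) * self.spacing_mm

    def index_of(self, position_mm):
        """Nearest voxel index of a physical position; errors if outside."""
        idx = np.round((np.asarray(position_mm, float) - self.origin_mm)
                       / self.spacing_mm).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise ValueError(f"position {position_mm} outside volume")
        return idx

    def contains(self, position_mm) -> bool:
        rel = (np.asarray(position_mm, float) - self.origin_mm) / self.spacing_mm
        return bool(np.all(rel >= -0.5) and
                    np.all(rel <= np.array(self.shape) - 0.5))

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.values.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in self.spacing_mm))
        img.SetOrigin(tuple(float(o) for o in self.origin_mm))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, subject_id: str = "") -> "PetVolume":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(values=arr, spacing_mm=np.array(img.GetSpacing()),
                   origin_mm=np.array(img.GetOrigin()), subject_id=subject_id)


def write_nrrd(volume: PetVolume, path) -> None:
    """Write a volume as an uncompressed NRRD file with spacing metadata."""
    path = os.fspath(path)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    writer = sitk.ImageFileWriter()
    writer.SetFileName(path)
    writer.SetUseCompression(False)
    writer.Execute(volume.to_sitk())


def read_nrrd(path, subject_id: str = "") -> PetVolume:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as e:  # pragma: no cover - message passthrough
        raise IOError(f"malformed NRRD file {path}: {e}") from e
    if not subject_id:
        subject_id = os.path.splitext(os.path.basename(path))[0]
    return PetVolume.from_sitk(img, subject_id=subject_id)


@dataclass
class NoduleAnnotation:
    """Ground-truth nodule record: centre (mm), diameter (mm) and class."""

    center_mm: np.ndarray
    diameter_mm: float
    label: str

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=np.float64)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if not (8.0 < self.diameter_mm <= 30.0):
            raise ValueError("diameter outside the 8-30 mm eligibility range")


@dataclass
class CohortManifest:
    """Ordered table of (volume path, annotation, subject id) records."""

    records: pd.DataFrame
    seed: int = 0

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest missing column(s): {', '.join(missing)}")
        bad = set(self.records["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown label(s) in manifest: {sorted(bad)}")

    def __len__(self):
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return (self.records["label"] == "malignant").to_numpy(dtype=int)

    def annotation(self, i: int) -> NoduleAnnotation:
        row = self.records.iloc[i]
        return NoduleAnnotation(
            center_mm=np.array([row.center_x_mm, row.center_y_mm,
                                row.center_z_mm]),
            diameter_mm=float(row.diameter_mm), label=str(row.label))

    def write_csv(self, path) -> None:
        self.records[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path, seed: int = 0) -> CohortManifest:
    """Read a manifest CSV; relative volume paths resolve against it."""
    path = os.fspath(path)
    df = pd.read_csv(path)
    manifest = CohortManifest(records=df, seed=seed)
    base = os.path.dirname(os.path.abspath(path))
    df["path"] = [p if os.path.isabs(p) else os.path.join(base, p)
                  for p in df["path"]]
    return manifest
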