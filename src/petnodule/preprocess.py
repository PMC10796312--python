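"""Resampling, nodule-centred cropping and fold-wise min-max normalisation.

The preprocessing contract mirrors the acquisition protocol: volumes are
resampled to 1.5 mm isotropic voxels with trilinear interpolation, a
60 mm cube (40 voxels per side) centred on the nodule is cropped with
zero fill outside the grid, and intensities are scaled to [0, 1] with
min-max statistics computed over *all* voxels of the training tensors of
a fold — validation and test tensors reuse the training statistics and may
therefore fall outside [0, 1] (they are not clipped unless asked).

Crop centring with an even side length is fixed by convention: the voxel
nearest the nodule centre occupies index ``side//2`` (20 for a 40-voxel
cube) on each axis.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import SimpleITK as sitk

from .volume import PetVolume

TENSOR_SHAPE = (40, 40, 40)


@dataclass
class InputTensor:
    """A 40x40x40 single-channel network input with provenance."""

    values: np.ndarray
    subject_id: str = ""
    fold_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != TENSOR_SHAPE:
            raise ValueError(
                f"input tensor must be {TENSOR_SHAPE}, got {self.values.shape}")


@dataclass
class NormStats:
    """Global min/max over every voxel of a fold's training tensors."""

    min_value: float
    max_value: float
    fold_id: str = ""

    def __post_init__(self):
        if not self.max_value > self.min_value:
            raise ValueError("degenerate normalisation: max must exceed min")

    def to_json(self) -> str:
        return json.dumps({"min_value": self.min_value,
                           "max_value": self.max_value,
                           "fold_id": self.fold_id})

    @classmethod
    def from_json(cls, text: str) -> "NormStats":
        return cls(**json.loads(text))


def resample_isotropic(volume: PetVolume, target_mm: float = 1.5) -> PetVolume:
    """Resample to isotropic spacing with trilinear interpolation.

    The output grid keeps the input origin; its size is chosen so that all
    sample points lie inside the input grid (no extrapolation), preserving
    the physical extent to within one voxel.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    if not np.all(np.isfinite(volume.values)):
        raise ValueError("non-finite intensities cannot be resampled")
    old_extent = volume.extent_mm()
    new_size = tuple(int(np.floor(e / target_mm)) + 1 for e in old_extent)
    img = volume.to_sitk()
    resampler = sitk.ResampleImageFilter()
    resampler.SetInterpolator(sitk.sitkLinear)
    resampler.SetOutputSpacing((float(target_mm),) * 3)
    resampler.SetOutputOrigin(img.GetOrigin())
    resampler.SetOutputDirection(img.GetDirection())
    resampler.SetSize(new_size)
    out = resampler.Execute(img)
    return PetVolume.from_sitk(out, subject_id=volume.subject_id)


def crop_cube(volume: PetVolume, center_mm, side_mm: float = 60.0) -> InputTensor:
    """Crop a ``side_mm`` cube centred on the voxel nearest ``center_mm``.

    Requires an (isotropically) resampled volume; out-of-grid regions are
    zero-filled.  60 mm at 1.5 mm spacing gives the 40-voxel network input.
    """
    spacing = volume.spacing_mm
    if not np.allclose(spacing, spacing[0]):
        raise ValueError("crop_cube expects an isotropically resampled volume")
    center_idx = volume.index_of(center_mm)  # raises if centre outside
    side_vox = int(round(side_mm / spacing[0]))
    start = center_idx - side_vox // 2
    out = np.zeros((side_vox,) * 3, dtype=np.float64)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + side_vox, volume.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
            volume.values[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1],
                          src_lo[2]:src_hi[2]]
    return InputTensor(values=out, subject_id=volume.subject_id)


def _stack(tensors) -> np.ndarray:
    arrs = [t.values if isinstance(t, InputTensor) else np.asarray(t)
            for t in tensors]
    return np.stack(arrs)


def fit_minmax(training, fold_id: str = "") -> NormStats:
    """Global scalar min/max over every voxel of every training tensor."""
    if len(training) == 0:
        raise ValueError("cannot fit normalisation on an empty training list")
    stacked = _stack(training)
    lo, hi = float(stacked.min()), float(stacked.max())
    if hi == lo:
        raise ValueError("degenerate normalisation: all training voxels equal")
    return NormStats(min_value=lo, max_value=hi, fold_id=fold_id)


def apply_minmax(tensor, stats: NormStats, clip: bool = False):
    """v' = (v - min) / (max - min); optionally clipped into [0, 1].

    Accepts an :class:`InputTensor` or a bare array and returns the same
    kind.  Validation/test values outside the training range are preserved
    unless ``clip`` is requested.
    """
    arr = tensor.values if isinstance(tensor, InputTensor) else np.asarray(tensor)
    out = (arr - stats.min_value) / (stats.max_value - stats.min_value)
    if clip:
        out = np.clip(out, 0.0, 1.0)
    if isinstance(tensor, InputTensor):
        return InputTensor(values=out, subject_id=tensor.subject_id,
                           fold_id=stats.fold_id or tensor.fold_id)
    return out


def invert_minmax(tensor, stats: NormStats):
    """Inverse of :func:`apply_minmax` (without clipping)."""
    arr = tensor.values if isinstance(tensor, InputTensor) else np.asarray(tensor)
    out = arr * (stats.max_value - stats.min_value) + stats.min_value
    if isinstance(tensor, InputTensor):
        return InputTensor(values=out, subject_id=tensor.subject_id,
                           fold_id=tensor.fold_id)
    return out
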