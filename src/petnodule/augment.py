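"""Offline class-balanced 3D augmentation: shifts, rotations, noise.

Each augmented example carries exactly one transform, applied to the
original (normalised) tensor:

* integer translations up to +/-10 voxels per axis (15 mm at 1.5 mm
  spacing), vacated voxels zero-filled;
* rotations about one tensor-centre axis, angle uniform in [-45, 45]
  degrees (near-identity angles below 1 degree excluded), implemented as
  the composite translate-to-centre / rotate / translate-back operation
  with bilinear interpolation in the slices perpendicular to the rotation
  axis and zero fill outside the grid;
* additive zero-mean Gaussian noise with sigma in {0.1, 0.3, 0.5} on the
  normalised intensity scale.

The per-class augmentation factors perform class balancing: the minority
(malignant) class receives 20 translations, 21 rotations (7 per axis) and
20 noisy copies (7, 7, 6 for sigma 0.1, 0.3, 0.5); the majority class 16,
15 (5 per axis) and 16 (6, 5, 5).  One original thus yields 61 (minority)
or 47 (majority) augmented tensors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import rotate as _nd_rotate

NOISE_SIGMAS = (0.1, 0.3, 0.5)
ROTATION_AXES = ("x", "y", "z")
# in-plane axis pairs for a rotation about each axis of an [x, y, z] array
_PLANES = {"x": (1, 2), "y": (0, 2), "z": (0, 1)}


@dataclass
class ClassPlan:
    """Augmentation factors for one class."""

    n_translations: int
    n_rotations_per_axis: int
    noise_counts: dict  # sigma -> count

    def __post_init__(self):
        if self.n_translations < 0 or self.n_rotations_per_axis < 0:
            raise ValueError("augmentation counts must be >= 0")
        if any(c < 0 for c in self.noise_counts.values()):
            raise ValueError("noise counts must be >= 0")

    @property
    def n_rotations(self) -> int:
        return 3 * self.n_rotations_per_axis

    @property
    def n_noise(self) -> int:
        return sum(self.noise_counts.values())

    @property
    def total(self) -> int:
        return self.n_translations + self.n_rotations + self.n_noise


@dataclass
class AugmentationPlan:
    """Per-class factors plus transform parameter ranges."""

    minority: ClassPlan = field(default_factory=lambda: ClassPlan(
        20, 7, {0.1: 7, 0.3: 7, 0.5: 6}))
    majority: ClassPlan = field(default_factory=lambda: ClassPlan(
        16, 5, {0.1: 6, 0.3: 5, 0.5: 5}))
    translation_range_vox: int = 10
    rotation_range_deg: float = 45.0
    min_rotation_deg: float = 1.0
    seed: int = 0

    def for_class(self, cls: str) -> ClassPlan:
        if cls == "minority":
            return self.minority
        if cls == "majority":
            return self.majority
        raise ValueError(f"class must be 'minority' or 'majority', got {cls!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "minority": {"n_translations": self.minority.n_translations,
                         "n_rotations_per_axis": self.minority.n_rotations_per_axis,
                         "noise_counts": {float(k): int(v) for k, v in
                                          self.minority.noise_counts.items()}},
            "majority": {"n_translations": self.majority.n_translations,
                         "n_rotations_per_axis": self.majority.n_rotations_per_axis,
                         "noise_counts": {float(k): int(v) for k, v in
                                          self.majority.noise_counts.items()}},
            "translation_range_vox": self.translation_range_vox,
            "rotation_range_deg": self.rotation_range_deg,
            "min_rotation_deg": self.min_rotation_deg,
            "seed": self.seed}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "AugmentationPlan":
        d = yaml.safe_load(text)
        return cls(minority=ClassPlan(**d["minority"]),
                   majority=ClassPlan(**d["majority"]),
                   translation_range_vox=d["translation_range_vox"],
                   rotation_range_deg=d["rotation_range_deg"],
                   min_rotation_deg=d.get("min_rotation_deg", 1.0),
                   seed=d["seed"])


def translate(tensor: np.ndarray, shift_vox, max_shift: int = 10) -> np.ndarray:
    """Displace contents by an integer shift per axis; zero-fill vacated voxels."""
    tensor = np.asarray(tensor)
    shift = tuple(int(s) for s in shift_vox)
    if len(shift) != 3:
        raise ValueError("shift must have three components")
    if any(abs(s) > max_shift for s in shift):
        raise ValueError(f"|shift| must be <= {max_shift} voxels, got {shift}")
    out = np.zeros_like(tensor)
    if any(abs(s) >= n for s, n in zip(shift, tensor.shape)):
        return out  # contents displaced entirely out of the grid
    src = []
    dst = []
    for s, n in zip(shift, tensor.shape):
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = tensor[tuple(src)]
    return out


def rotate(tensor: np.ndarray, axis: str, angle_deg: float) -> np.ndarray:
    """Rotate about one tensor-centre axis with in-plane bilinear interpolation."""
    if axis not in _PLANES:
        raise ValueError(f"axis must be one of {ROTATION_AXES}, got {axis!r}")
    if not -45.0 <= angle_deg <= 45.0:
        raise ValueError("rotation angle must lie in [-45, 45] degrees")
    return _nd_rotate(np.asarray(tensor, dtype=np.float64), angle_deg,
                      axes=_PLANES[axis], reshape=False, order=1,
                      mode="constant", cval=0.0)


def add_noise(tensor: np.ndarray, sigma: float,
              rng: np.random.Generator) -> np.ndarray:
    """Additive i.i.d. zero-mean Gaussian noise per voxel."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    tensor = np.asarray(tensor, dtype=np.float64)
    if sigma == 0:
        return tensor.copy()
    return tensor + rng.normal(0.0, sigma, size=tensor.shape)


def _draw_shift(rng, max_shift):
    while True:
        s = rng.integers(-max_shift, max_shift + 1, size=3)
        if np.any(s != 0):
            return tuple(int(v) for v in s)


def _draw_angle(rng, lo_exclude, rng_deg):
    while True:
        a = float(rng.uniform(-rng_deg, rng_deg))
        if abs(a) >= lo_exclude:
            return a


def augment_subject(tensor: np.ndarray, cls: str, plan: AugmentationPlan,
                    rng: np.random.Generator, return_records: bool = False):
    """All augmented copies of one subject tensor under the class plan.

    Returns exactly ``translations + rotations + noise`` tensors (61 for
    the minority plan, 47 for the majority plan at the default factors);
    rotations are apportioned evenly over the three axes.
    """
    cp = plan.for_class(cls)
    out, records = [], []
    for _ in range(cp.n_translations):
        shift = _draw_shift(rng, plan.translation_range_vox)
        out.append(translate(tensor, shift, plan.translation_range_vox))
        records.append({"transform": "translate", "shift_vox": shift})
    for axis in ROTATION_AXES:
        for _ in range(cp.n_rotations_per_axis):
            ang = _draw_angle(rng, plan.min_rotation_deg, plan.rotation_range_deg)
            out.append(rotate(tensor, axis, ang))
            records.append({"transform": "rotate", "axis": axis,
                            "angle_deg": ang})
    for sigma in sorted(cp.noise_counts):
        for _ in range(cp.noise_counts[sigma]):
            out.append(add_noise(tensor, sigma, rng))
            records.append({"transform": "noise", "sigma": float(sigma)})
    if return_records:
        return out, records
    return out


def subject_seed(plan_seed: int, subject_id: str) -> int:
    """Stable per-subject sub-seed: plan seed XOR CRC32 of the subject id."""
    return (int(plan_seed) ^ zlib.crc32(str(subject_id).encode())) & 0x7FFFFFFF


def minority_label(labels) -> object:
    """The less frequent label; ties resolve to 'malignant' when present."""
    vals, counts = np.unique(np.asarray(labels), return_counts=True)
    if len(vals) > 2:
        raise ValueError("binary labels expected")
    order = np.argsort(counts)
    if len(vals) == 2 and counts[0] == counts[1]:
        if "malignant" in vals:
            return "malignant"
    return vals[order[0]]


def build_augmented_dataset(tensors, labels, plan: AugmentationPlan,
                            subject_ids=None):
    """Originals plus all augmented copies, labels preserved.

    ``labels`` may be any binary labelling; the minority class receives
    the minority plan.  Per-subject RNG streams derive from the plan seed
    and the subject id, so the dataset is reproducible subject-by-subject.
    Returns ``(tensor_list, label_list)``.
    """
    labels = list(labels)
    tensors = [np.asarray(t) for t in tensors]
    if len(tensors) != len(labels):
        raise ValueError("tensors and labels must align")
    if not tensors:
        return [], []
    uniq = set(labels)
    if len(uniq) > 2:
        raise ValueError(f"binary labels expected, got {sorted(map(str, uniq))}")
    mino = minority_label(labels)
    if subject_ids is None:
        subject_ids = [str(i) for i in range(len(tensors))]
    out_t, out_y = [], []
    for t, y, sid in zip(tensors, labels, subject_ids):
        out_t.append(t)
        out_y.append(y)
        cls = "minority" if y == mino else "majority"
        rng = np.random.default_rng(subject_seed(plan.seed, sid))
        aug = augment_subject(t, cls, plan, rng)
        out_t.extend(aug)
        out_y.extend([y] * len(aug))
    return out_t, out_y


def augmented_count(n_minority: int, n_majority: int,
                    plan: AugmentationPlan) -> int:
    """Closed-form dataset size: originals plus per-class augmentations."""
    return (n_minority * (1 + plan.minority.total)
            + n_majority * (1 + plan.majority.total))
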