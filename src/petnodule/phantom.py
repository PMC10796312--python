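"""Seeded PET nodule phantom cohorts.

The generator emulates the statistical structure of an FDG-PET pulmonary
nodule cohort: ~113 subjects with one solid nodule each, 45.1% malignant
prevalence, nodule diameters with median 13 mm (IQR 5 mm) restricted to
the 8-30 mm eligibility window, and malignant nodules showing higher
nodule-to-background tracer uptake than benign ones, with class overlap.

Each phantom volume is built on an anisotropic native grid (as delivered
by clinical scanners, which is why isotropic resampling exists downstream):

1. uniform physiological background uptake (1 SUV by default);
2. one ellipsoidal nodule near the volume centre whose per-axis radii are
   the sampled diameter/2 jittered +/-20%, filled with
   ``background * contrast`` where the contrast ratio is a class-conditional
   log-normal draw (median 4.0 malignant, 1.5 benign, log-sd 0.35),
   clipped below at 1 so nodules are never colder than background;
3. a configurable number of peripheral "distractor" hot spots emulating
   physiological uptake away from the nodule;
4. Gaussian smoothing with a 6 mm FWHM point-spread function, the typical
   reconstructed PET resolution, producing realistic partial-volume
   contrast loss for small nodules;
5. additive Gaussian noise truncated at zero (SUV non-negativity).

Diameters are drawn from a log-normal law parameterised in closed form to
match the printed median and IQR, rejected outside (8, 30] mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import (CohortManifest, MANIFEST_COLUMNS, NoduleAnnotation,
                     PetVolume, write_nrrd)

_Q75 = 0.674489750196082  # standard normal upper quartile


@dataclass
class PhantomSpec:
    """Parameters of a phantom cohort; defaults are the study conditions."""

    n_subjects: int = 113
    prevalence: float = 0.451
    diameter_median_mm: float = 13.0
    diameter_iqr_mm: float = 5.0
    voxel_mm: float = 1.5                    # target isotropic spacing
    field_mm: tuple = (90.0, 90.0, 90.0)     # physical extent per axis
    contrast_malignant: float = 4.0
    contrast_benign: float = 1.5
    contrast_sd: float = 0.35                # log-scale dispersion
    n_distractors: int = 3
    noise_sd: float = 0.1                    # additive SUV noise
    seed: int = 0
    # native scanner grid the phantom is synthesised on (anisotropic)
    native_spacing_mm: tuple = (2.0, 2.0, 3.0)
    background_suv: float = 1.0
    psf_fwhm_mm: float = 6.0
    center_jitter_mm: float = 3.0
    diameter_range_mm: tuple = (8.0, 30.0)

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if self.diameter_median_mm <= 0 or self.diameter_iqr_mm <= 0:
            raise ValueError("diameters must be positive")
        if not (self.contrast_malignant > self.contrast_benign >= 1.0):
            raise ValueError("need contrast_malignant > contrast_benign >= 1")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def diameter_log_sd(self) -> float:
        """Log-normal sigma matching the requested median and IQR exactly
        (before truncation): IQR = median*(t - 1/t) with t = exp(q75*sigma)."""
        r = self.diameter_iqr_mm / self.diameter_median_mm
        t = (r + np.sqrt(r * r + 4.0)) / 2.0
        return float(np.log(t) / _Q75)


def sample_diameter(spec: PhantomSpec, rng: np.random.Generator) -> float:
    """One nodule diameter from the truncated log-normal size law."""
    mu = np.log(spec.diameter_median_mm)
    sd = spec.diameter_log_sd
    lo, hi = spec.diameter_range_mm
    for _ in range(1000):
        d = float(np.exp(rng.normal(mu, sd)))
        if lo < d <= hi:
            return d
    raise RuntimeError("diameter sampling failed; check the size law")


def _grid_coords(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec, label: str,
                     rng: np.random.Generator,
                     subject_id: str = "phantom"):
    """One phantom volume plus its ground-truth annotation.

    Returns ``(PetVolume, NoduleAnnotation)``.  The volume lives on the
    native anisotropic grid with origin 0; the annotation records the true
    nodule centre (mm), sampled diameter and class label.
    """
    if label not in ("benign", "malignant"):
        raise ValueError(f"unknown label {label!r}")
    spacing = np.asarray(spec.native_spacing_mm, dtype=float)
    field = np.asarray(spec.field_mm, dtype=float)
    shape = tuple(int(np.floor(f / s)) + 1 for f, s in zip(field, spacing))
    extent = (np.array(shape) - 1) * spacing

    diameter = sample_diameter(spec, rng)
    if diameter >= float(np.min(extent)):
        raise ValueError(
            f"nodule diameter {diameter:.1f} mm exceeds field extent")

    center = extent / 2.0 + rng.uniform(-spec.center_jitter_mm,
                                        spec.center_jitter_mm, size=3)
    radii = (diameter / 2.0) * (1.0 + rng.uniform(-0.2, 0.2, size=3))
    base = spec.contrast_malignant if label == "malignant" else spec.contrast_benign
    contrast = float(np.exp(rng.normal(np.log(base), spec.contrast_sd)))
    contrast = max(contrast, 1.0)

    bg = spec.background_suv
    vol = np.full(shape, bg, dtype=np.float64)
    gx, gy, gz = _grid_coords(shape, spacing)
    dist2 = (((gx - center[0]) / radii[0]) ** 2 +
             ((gy - center[1]) / radii[1]) ** 2 +
             (((gz - center[2]) / radii[2]) ** 2))
    vol[dist2 <= 1.0] = bg * contrast

    for _ in range(spec.n_distractors):
        # peripheral physiological hot spot, kept away from the nodule
        for _attempt in range(100):
            pos = rng.uniform(5.0, extent - 5.0)
            if np.linalg.norm(pos - center) >= max(15.0, diameter):
                break
        amp = bg * rng.uniform(1.0, 3.0)
        sig = rng.uniform(2.0, 4.0)
        d2 = ((gx - pos[0]) ** 2 + (gy - pos[1]) ** 2 + (gz - pos[2]) ** 2)
        vol += amp * np.exp(-d2 / (2.0 * sig ** 2))

    if spec.psf_fwhm_mm > 0:
        sigma_vox = (spec.psf_fwhm_mm / 2.354820045) / spacing
        vol = gaussian_filter(vol, sigma=sigma_vox)

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
    vol = np.maximum(vol, 0.0)

    volume = PetVolume(values=vol, spacing_mm=spacing,
                       origin_mm=np.zeros(3), subject_id=subject_id)
    annotation = NoduleAnnotation(center_mm=center, diameter_mm=diameter,
                                  label=label)
    return volume, annotation


def cohort_labels(n_subjects: int, prevalence: float,
                  rng: np.random.Generator) -> list[str]:
    """Label list with exactly round(n * prevalence) malignant subjects."""
    n_mal = int(round(n_subjects * prevalence))
    labels = np.array(["malignant"] * n_mal +
                      ["benign"] * (n_subjects - n_mal))
    rng.shuffle(labels)
    return labels.tolist()


def generate_cohort(spec: PhantomSpec, out_dir) -> CohortManifest:
    """Write a full phantom cohort (NRRD volumes + CSV manifest).

    Per-subject random streams are spawned from the cohort seed, so the
    cohort is bit-reproducible and each subject is independent of cohort
    ordering.
    """
    out_dir = Path(out_dir)
    try:
        (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {out_dir}: {e}") from e

    ss = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_streams = np.random.SeedSequence(spec.seed + 1).spawn(spec.n_subjects)
    labels = cohort_labels(spec.n_subjects, spec.prevalence, label_rng)

    rows = []
    for i, label in enumerate(labels):
        sid = f"s{i + 1:03d}"
        rng = np.random.default_rng(subject_streams[i])
        volume, ann = generate_phantom(spec, label, rng, subject_id=sid)
        rel_path = f"volumes/{sid}.nrrd"
        write_nrrd(volume, out_dir / rel_path)
        rows.append({
            # relative to the manifest location, so cohorts are relocatable
            "subject_id": sid, "path": rel_path, "label": label,
            "center_x_mm": ann.center_mm[0], "center_y_mm": ann.center_mm[1],
            "center_z_mm": ann.center_mm[2], "diameter_mm": ann.diameter_mm,
        })
    manifest = CohortManifest(records=pd.DataFrame(rows, columns=MANIFEST_COLUMNS),
                              seed=spec.seed)
    manifest.write_csv(out_dir / "manifest.csv")
    # resolve paths for in-memory use; the CSV keeps them relative
    manifest.records["path"] = [str(out_dir / p)
                                for p in manifest.records["path"]]
    return manifest


def suvmax_score(volume: PetVolume, annotation: NoduleAnnotation) -> float:
    """Maximum voxel SUV inside the annotated nodule sphere.

    The sphere has the annotated diameter and is centred at the annotated
    centre; this is the conventional SUVmax biomarker the CNN is compared
    against.
    """
    if not volume.contains(annotation.center_mm):
        raise ValueError("annotation centre lies outside the volume")
    gx, gy, gz = _grid_coords(volume.shape, volume.spacing_mm)
    c = annotation.center_mm - volume.origin_mm
    r = annotation.diameter_mm / 2.0
    mask = ((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) <= r * r
    if not mask.any():
        raise ValueError("nodule sphere contains no voxel centre")
    return float(volume.values[mask].max())
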