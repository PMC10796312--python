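"""Simulate a small phantom PET cohort and inspect its structure.

Generates 20 subjects with the default study conditions (45.1% malignant
prevalence, 13 mm median nodule diameter, higher uptake in malignant
nodules), writes NRRD volumes plus a CSV manifest, and prints the size
and SUVmax distributions per class.
"""

import numpy as np

from petnodule import PhantomSpec, generate_cohort, read_nrrd, suvmax_score

spec = PhantomSpec(n_subjects=20, seed=42)
manifest = generate_cohort(spec, "runs/example_cohort")

print(f"cohort of {len(manifest)} subjects, "
      f"{manifest.labels.sum()} malignant")
for label in ("malignant", "benign"):
    rows = manifest.records[manifest.records.label == label]
    suv = []
    for i in rows.index:
        vol = read_nrrd(manifest.records.loc[i, "path"])
        suv.append(suvmax_score(vol, manifest.annotation(i)))
    print(f"  {label:9s}: n={len(rows):2d} "
          f"diameter median {rows.diameter_mm.median():.1f} mm, "
          f"SUVmax mean {np.mean(suv):.2f}")

# Malignant nodules should show clearly higher SUVmax on average (their
# contrast ratio is drawn around 4.0 vs 1.5 for benign), with overlap
# between the classes so the classification task stays non-trivial.
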