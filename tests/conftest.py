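import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from petnodule.models import ArchitectureSpec
from petnodule.phantom import PhantomSpec, generate_phantom
from petnodule.preprocess import crop_cube, resample_isotropic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_training_spec(l2=0.0):
    """A miniature architecture on 9^3 inputs for fast optimisation tests."""
    return ArchitectureSpec(
        family="stacked3d",
        layers=[
            {"kind": "conv", "filters": 4, "kernel": 3, "stride": 1,
             "padding": "valid", "activation": "leaky_relu"},
            {"kind": "mpool", "pool": 2, "stride": 2, "padding": "valid"},
            {"kind": "flatten"},
            {"kind": "dense", "units": 8, "activation": "leaky_relu"},
            {"kind": "dense", "units": 1, "activation": "linear"},
        ],
        l2_lambda=l2, input_shape=(9, 9, 9))


@pytest.fixture(scope="session")
def phantom_crops():
    """Sixteen preprocessed 40^3 crops (8 malignant / 8 benign) with a
    clear uptake contrast; shared by training-level tests."""
    spec = PhantomSpec(noise_sd=0.05, n_distractors=1,
                       contrast_malignant=6.0, contrast_benign=1.3,
                       contrast_sd=0.1)
    rng = np.random.default_rng(77)
    crops, labels, annotations = [], [], []
    for i in range(16):
        label = "malignant" if i % 2 == 0 else "benign"
        vol, ann = generate_phantom(spec, label, rng, f"s{i:02d}")
        iso = resample_isotropic(vol, spec.voxel_mm)
        crops.append(crop_cube(iso, ann.center_mm).values)
        labels.append(1 if label == "malignant" else 0)
        annotations.append(ann)
    return crops, np.array(labels), annotations
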