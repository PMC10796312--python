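"""Declarative 3D CNN architecture specifications and builders.

Three families are provided, all taking a single-channel 40x40x40 input and
ending in one sigmoid unit:

* ``stacked3d`` — four valid-padding 3^3 convolutions (8, 16, 32, 64
  filters) alternating with 2^3/stride-2 max-pools, then dense 32-16-1.
  Spatial size chain: 40 -> 38 -> 19 -> 17 -> 8 -> 6 -> 3 -> 1.
* ``vgg_like`` — stacked 3^3 valid convolutions with overlapping
  same-padded 3^3/stride-2 max-pools; larger kernels are factorised into
  stacks of 3^3 (two for a 5^3 receptive field, three for 7^3), which cuts
  the parameter count while preserving the receptive field.
* ``inception_like`` — a 3^3 stem then four standard inception modules and
  two reduction modules, ending in global average pooling.  Standard
  modules run four parallel branches (1^3, factorised 3^3 stacks, pooled
  1^3) concatenated channel-wise; reduction modules downsample with
  stride-2 branches.

Activations are LeakyReLU (alpha = 0.3) on every convolution and hidden
dense layer; the output unit is linear (a sigmoid is applied on top of the
logit at prediction time).  Kernels are He-initialised; L2 weight decay
applies to kernels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .nn import (Adam, ConcatBranches, Conv3D, Dense, Flatten,
                 GlobalAvgPool3D, LeakyReLU, MaxPool3D, Network, same_padding)

INPUT_SHAPE = (40, 40, 40)

# branch widths of the standard inception modules before / after the first
# reduction stage; declared here so alternates are a one-line change
INCEPTION_WIDTH_STAGE1 = 8
INCEPTION_WIDTH_STAGE2 = 16


@dataclass
class ArchitectureSpec:
    """Declarative network definition (layer list plus conventions)."""

    family: str
    layers: list = field(default_factory=list)
    leaky_alpha: float = 0.3
    l2_lambda: float = 0.0
    init_scheme: str = "he"
    input_shape: tuple = INPUT_SHAPE

    def to_yaml(self) -> str:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        d = yaml.safe_load(text)
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


@dataclass
class TrainedModel:
    """A fitted network together with its training history."""

    spec: ArchitectureSpec
    network: Network
    history: dict = field(default_factory=dict)
    best_epoch: int = -1
    norm_stats: Optional[object] = None  # NormStats of the training fold

    def predict_proba(self, x, batch_size=32):
        return self.network.predict_proba(
            _as_batch(x, tuple(self.spec.input_shape)), batch_size=batch_size)


def _as_batch(x, expected=INPUT_SHAPE):
    x = np.asarray(x)
    if x.ndim == 3:
        x = x[None]
    if x.ndim == 4:  # (N, d0, d1, d2) -> add channel axis
        x = x[:, None]
    if x.ndim != 5:
        raise ValueError(f"expected 3D volumes, got shape {x.shape}")
    if x.shape[2:] != tuple(expected):
        raise ValueError(f"expected spatial shape {expected}, got {x.shape[2:]}")
    return x


def forward(model: TrainedModel, batch) -> np.ndarray:
    """Probabilities in (0,1), one per input volume; deterministic."""
    return model.predict_proba(batch)


def save_model(model: TrainedModel, prefix) -> None:
    """Persist a trained model: weights (npz) + spec/history (JSON)."""
    import json
    from pathlib import Path
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    weights = model.network.get_weights()
    np.savez(str(prefix) + ".npz", **{f"w{i}": w for i, w in enumerate(weights)})
    meta = {"spec_yaml": model.spec.to_yaml(),
            "history": model.history, "best_epoch": model.best_epoch}
    if model.norm_stats is not None:
        meta["norm_stats"] = json.loads(model.norm_stats.to_json())
    (prefix.parent / (prefix.name + ".json")).write_text(json.dumps(meta))


def load_model(prefix) -> TrainedModel:
    import json
    from pathlib import Path
    from .preprocess import NormStats
    prefix = Path(prefix)
    meta = json.loads((prefix.parent / (prefix.name + ".json")).read_text())
    spec = ArchitectureSpec.from_yaml(meta["spec_yaml"])
    net = build_network(spec, rng=np.random.default_rng(0))
    with np.load(str(prefix) + ".npz") as z:
        net.set_weights([z[f"w{i}"] for i in range(len(z.files))])
    stats = (NormStats(**meta["norm_stats"]) if "norm_stats" in meta else None)
    return TrainedModel(spec=spec, network=net, history=meta["history"],
                        best_epoch=meta["best_epoch"], norm_stats=stats)


# ---------------------------------------------------------------------------
# builders


def _conv(filters, kernel=3, stride=1, padding="valid", activation="leaky_relu"):
    return {"kind": "conv", "filters": int(filters), "kernel": int(kernel),
            "stride": int(stride), "padding": padding, "activation": activation}


def _pool(pool=2, stride=2, padding="valid"):
    return {"kind": "mpool", "pool": int(pool), "stride": int(stride),
            "padding": padding}


def _dense(units, activation="leaky_relu"):
    return {"kind": "dense", "units": int(units), "activation": activation}


def _inception(width):
    return {"kind": "inception", "width": int(width)}


def _reduction(width):
    return {"kind": "reduction", "width": int(width)}


def build_stacked3d(l2_lambda: float = 0.00098) -> ArchitectureSpec:
    """Four conv/pool stages then dense 32-16-1 (the final-model family)."""
    if l2_lambda < 0:
        raise ValueError("l2_lambda must be >= 0")
    layers = [
        _conv(8), _pool(), _conv(16), _pool(), _conv(32), _pool(), _conv(64),
        {"kind": "flatten"},
        _dense(32), _dense(16), _dense(1, activation="linear"),
    ]
    return ArchitectureSpec("stacked3d", layers, l2_lambda=l2_lambda)


def build_vgg_like(l2_lambda: float = 0.002) -> ArchitectureSpec:
    """Factorised 3^3 stacks with overlapping same-padded pooling."""
    if l2_lambda < 0:
        raise ValueError("l2_lambda must be >= 0")
    layers = [
        _conv(8), _pool(3, 2, "same"),
        _conv(16), _conv(16), _pool(3, 2, "same"),
        _conv(32), _conv(32), _conv(32), _pool(3, 2, "same"),
        {"kind": "flatten"},
        _dense(1, activation="linear"),
    ]
    return ArchitectureSpec("vgg_like", layers, l2_lambda=l2_lambda)


def build_vgg_unfactorised(l2_lambda: float = 0.002) -> ArchitectureSpec:
    """The vgg_like network with each stack of 3^3 convolutions replaced by
    a single convolution of equal receptive field (5^3 for the pair, 7^3
    for the triple).  Used to quantify the parameter saving of
    factorisation; not a trained model family."""
    layers = [
        _conv(8), _pool(3, 2, "same"),
        _conv(16, kernel=5), _pool(3, 2, "same"),
        _conv(32, kernel=7), _pool(3, 2, "same"),
        {"kind": "flatten"},
        _dense(1, activation="linear"),
    ]
    return ArchitectureSpec("vgg_unfactorised", layers, l2_lambda=l2_lambda)


def build_inception_like(l2_lambda: float = 0.0006) -> ArchitectureSpec:
    """Stem + 2x(standard, standard, reduction) + GAP + sigmoid unit."""
    if l2_lambda < 0:
        raise ValueError("l2_lambda must be >= 0")
    w1, w2 = INCEPTION_WIDTH_STAGE1, INCEPTION_WIDTH_STAGE2
    layers = [
        _conv(8), _pool(),
        _inception(w1), _inception(w1), _reduction(w1),
        _inception(w2), _inception(w2), _reduction(w2),
        {"kind": "gap"},
        _dense(1, activation="linear"),
    ]
    return ArchitectureSpec("inception_like", layers, l2_lambda=l2_lambda)


BUILDERS = {
    "stacked3d": build_stacked3d,
    "vgg_like": build_vgg_like,
    "inception_like": build_inception_like,
}


# ---------------------------------------------------------------------------
# instantiation


def _inception_branches(in_ch, width, alpha, rng):
    half = max(width // 2, 1)
    return [
        [Conv3D(in_ch, width, 1, rng=rng), LeakyReLU(alpha)],
        [Conv3D(in_ch, half, 1, rng=rng), LeakyReLU(alpha),
         Conv3D(half, width, 3, padding="same", rng=rng), LeakyReLU(alpha)],
        [Conv3D(in_ch, half, 1, rng=rng), LeakyReLU(alpha),
         Conv3D(half, width, 3, padding="same", rng=rng), LeakyReLU(alpha),
         Conv3D(width, width, 3, padding="same", rng=rng), LeakyReLU(alpha)],
        [MaxPool3D(3, 1, padding="same"),
         Conv3D(in_ch, width, 1, rng=rng), LeakyReLU(alpha)],
    ]


def _reduction_branches(in_ch, width, alpha, rng):
    half = max(width // 2, 1)
    return [
        [Conv3D(in_ch, half, 1, rng=rng), LeakyReLU(alpha),
         Conv3D(half, width, 3, stride=2, padding="same", rng=rng),
         LeakyReLU(alpha)],
        [Conv3D(in_ch, half, 1, rng=rng), LeakyReLU(alpha),
         Conv3D(half, width, 3, padding="same", rng=rng), LeakyReLU(alpha),
         Conv3D(width, width, 3, stride=2, padding="same", rng=rng),
         LeakyReLU(alpha)],
        [MaxPool3D(3, 2, padding="same")],
    ]


def _module_out_channels(kind, width, in_ch):
    if kind == "inception":
        return 4 * width
    return 2 * width + in_ch  # reduction: two conv branches + pooled passthrough


def build_network(spec: ArchitectureSpec, rng=None) -> Network:
    """Instantiate the layers of a spec with He-initialised weights."""
    rng = rng or np.random.default_rng()
    alpha = spec.leaky_alpha
    layers = []
    channels = 1
    spatial = tuple(spec.input_shape)
    for ls in spec.layers:
        kind = ls["kind"]
        if kind == "conv":
            conv = Conv3D(channels, ls["filters"], ls["kernel"], ls["stride"],
                          ls["padding"], rng=rng)
            layers.append(conv)
            spatial = conv.output_shape(spatial)
            channels = ls["filters"]
            if ls["activation"] == "leaky_relu":
                layers.append(LeakyReLU(alpha))
        elif kind == "mpool":
            pool = MaxPool3D(ls["pool"], ls["stride"], ls["padding"])
            layers.append(pool)
            spatial = pool.output_shape(spatial)
        elif kind == "inception":
            layers.append(ConcatBranches(
                _inception_branches(channels, ls["width"], alpha, rng)))
            channels = _module_out_channels(kind, ls["width"], channels)
        elif kind == "reduction":
            layers.append(ConcatBranches(
                _reduction_branches(channels, ls["width"], alpha, rng)))
            channels = _module_out_channels(kind, ls["width"], channels)
            spatial = tuple(-(-d // 2) for d in spatial)
        elif kind == "flatten":
            layers.append(Flatten())
            channels = channels * int(np.prod(spatial))
            spatial = None
        elif kind == "gap":
            layers.append(GlobalAvgPool3D())
            spatial = None
        elif kind == "dense":
            layers.append(Dense(channels, ls["units"], rng=rng))
            channels = ls["units"]
            if ls["activation"] == "leaky_relu":
                layers.append(LeakyReLU(alpha))
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
    return Network(layers)


# ---------------------------------------------------------------------------
# arithmetic on specs (no instantiation)


def spatial_chain(spec: ArchitectureSpec) -> list[tuple]:
    """Spatial size after each conv/pool/module layer, starting at input."""
    spatial = tuple(spec.input_shape)
    chain = [spatial]
    for ls in spec.layers:
        kind = ls["kind"]
        if kind == "conv":
            k, s = ls["kernel"], ls["stride"]
            if ls["padding"] == "same":
                spatial = tuple(-(-d // s) for d in spatial)
            else:
                spatial = tuple((d - k) // s + 1 for d in spatial)
        elif kind == "mpool":
            k, s = ls["pool"], ls["stride"]
            if ls["padding"] == "same":
                spatial = tuple(-(-d // s) for d in spatial)
            else:
                spatial = tuple((d - k) // s + 1 for d in spatial)
        elif kind == "reduction":
            spatial = tuple(-(-d // 2) for d in spatial)
        elif kind in ("flatten", "gap"):
            break
        else:
            continue
        chain.append(spatial)
    return chain


def count_parameters(spec: ArchitectureSpec) -> int:
    """Exact trainable parameter count (weights + biases) of a spec."""
    total = 0
    channels = 1
    spatial = tuple(spec.input_shape)

    def conv_params(cin, cout, k):
        return cout * (cin * k ** 3 + 1)

    for ls in spec.layers:
        kind = ls["kind"]
        if kind == "conv":
            total += conv_params(channels, ls["filters"], ls["kernel"])
            k, s = ls["kernel"], ls["stride"]
            if ls["padding"] == "same":
                spatial = tuple(-(-d // s) for d in spatial)
            else:
                spatial = tuple((d - k) // s + 1 for d in spatial)
            channels = ls["filters"]
        elif kind == "mpool":
            k, s = ls["pool"], ls["stride"]
            if ls["padding"] == "same":
                spatial = tuple(-(-d // s) for d in spatial)
            else:
                spatial = tuple((d - k) // s + 1 for d in spatial)
        elif kind == "inception":
            w = ls["width"]
            half = max(w // 2, 1)
            total += conv_params(channels, w, 1)
            total += conv_params(channels, half, 1) + conv_params(half, w, 3)
            total += (conv_params(channels, half, 1) + conv_params(half, w, 3)
                      + conv_params(w, w, 3))
            total += conv_params(channels, w, 1)
            channels = 4 * w
        elif kind == "reduction":
            w = ls["width"]
            half = max(w // 2, 1)
            total += conv_params(channels, half, 1) + conv_params(half, w, 3)
            total += (conv_params(channels, half, 1) + conv_params(half, w, 3)
                      + conv_params(w, w, 3))
            channels = 2 * w + channels
            spatial = tuple(-(-d // 2) for d in spatial)
        elif kind == "flatten":
            channels = channels * int(np.prod(spatial))
            spatial = None
        elif kind == "gap":
            spatial = None
        elif kind == "dense":
            total += channels * ls["units"] + ls["units"]
            channels = ls["units"]
    return total
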