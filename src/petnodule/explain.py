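"""3D Grad-CAM saliency maps, thick-slice reformatting and fusion overlays.

Grad-CAM weights each channel of a convolutional feature map by the
spatial average of the gradient of the pre-sigmoid logit with respect to
that channel, sums the weighted maps, rectifies, trilinearly upsamples to
the 40^3 input grid and max-normalises to [0, 1].

The default source layer is the deepest convolutional output with spatial
extent above one voxel: for the stacked architecture the final conv map
is 1^3 (spatially uniform after upsampling, hence uninformative), so the
penultimate conv layer is used there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy.ndimage import map_coordinates

from .models import TrainedModel, _as_batch
from .nn.layers import Conv3D, ConcatBranches, MaxPool3D

HEATMAP_SHAPE = (40, 40, 40)
AXIAL_AXIS = 2  # z


@dataclass
class GradCamMap:
    """A [0,1]-normalised saliency volume aligned to the model input grid
    (40^3 for the production architectures)."""

    heatmap: np.ndarray
    layer_index: int
    model_id: str = ""

    def __post_init__(self):
        self.heatmap = np.asarray(self.heatmap, dtype=np.float64)
        if self.heatmap.ndim != 3:
            raise ValueError("heatmap must be a 3D volume")
        if self.heatmap.min() < 0:
            raise ValueError("heatmap must be non-negative")


def _feature_affine(layers, input_spatial):
    """Affine map feature-index -> input-index along each axis.

    Composes kernel/stride/padding geometry so that feature voxel ``i``
    has its receptive-field centre at input position ``a*i + b``.  For
    branch containers the first branch fixes the (shared) geometry.
    """
    a = np.ones(3)
    b = np.zeros(3)
    spatial = tuple(input_spatial)
    for layer in layers:
        if isinstance(layer, ConcatBranches):
            a, b, spatial = _feature_affine_branch(layer.branches[0], a, b,
                                                   spatial)
        elif isinstance(layer, (Conv3D, MaxPool3D)):
            a, b, spatial = _advance_affine(layer, a, b, spatial)
    return a, b


def _advance_affine(layer, a, b, spatial):
    k = layer.kernel if isinstance(layer, Conv3D) else layer.pool
    s = layer.stride
    pads = layer._pad_amounts(spatial)
    for ax in range(3):
        b[ax] = b[ax] + a[ax] * ((k[ax] - 1) / 2.0 - pads[ax][0])
        a[ax] = a[ax] * s[ax]
    return a, b, layer.output_shape(spatial)


def _feature_affine_branch(branch, a, b, spatial):
    for layer in branch:
        if isinstance(layer, (Conv3D, MaxPool3D)):
            a, b, spatial = _advance_affine(layer, a, b, spatial)
    return a, b, spatial


def _upsample_cam(cam, layers, input_shape):
    """Trilinear upsampling that places feature voxels at the centres of
    their receptive fields; the periphery clamps to the nearest value."""
    a, b = _feature_affine(layers, input_shape)
    grids = np.meshgrid(*[(np.arange(n) - b[i]) / a[i]
                          for i, n in enumerate(input_shape)], indexing="ij")
    out = map_coordinates(cam, np.stack([g.ravel() for g in grids]),
                          order=1, mode="nearest").reshape(input_shape)
    return np.maximum(out, 0.0)


def _default_cam_layer(network, x):
    """Deepest conv-like layer whose feature map keeps spatial extent > 1."""
    network.forward_logits(x[:1])
    best = None
    for i in network.conv_layer_indices():
        shape = network.output_shape_of(i)
        if len(shape) == 5 and min(shape[2:]) > 1:
            best = i
    if best is None:
        raise ValueError("no convolutional layer with spatial extent > 1")
    return best


def gradcam3d(model: TrainedModel, tensor, layer: int = None) -> GradCamMap:
    """Grad-CAM heatmap of one (normalised) input under one fold model.

    ``layer`` is an index into the network's layer list and must refer to
    a convolutional (or inception concat) layer; by default the deepest
    spatial conv layer is used.
    """
    net = model.network
    target_shape = tuple(model.spec.input_shape)
    x = _as_batch(np.asarray(tensor), target_shape)
    if layer is None:
        layer = _default_cam_layer(net, x)
    if not isinstance(net.layers[layer], (Conv3D, ConcatBranches)):
        raise ValueError(f"layer {layer} is not a convolutional layer")
    # forward with caches, keeping the target activation
    h = x
    act = None
    for i, lyr in enumerate(net.layers):
        h = lyr.forward(h, train=True)
        if i == layer:
            act = h
    if act is None or act.ndim != 5:
        raise ValueError(f"layer {layer} has no spatial feature map")
    grad = net.backward_to(layer, np.ones(1))  # d logit / d activation
    alpha = grad.mean(axis=(2, 3, 4))          # (1, C) channel weights
    cam = np.maximum((alpha[:, :, None, None, None] * act).sum(axis=1), 0.0)[0]
    cam = cam.astype(np.float64)
    if cam.shape != target_shape:
        cam = _upsample_cam(cam, net.layers[:layer + 1], target_shape)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return GradCamMap(heatmap=cam, layer_index=layer, model_id=model.spec.family)


def thick_slices(volume, n_out: int = 10) -> list[np.ndarray]:
    """Average the axial (z) slices down to ``n_out`` thick slices.

    The axial extent must be divisible by ``n_out``; each output slice is
    the mean of the corresponding consecutive group (4 slices for 40/10).
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    nz = vol.shape[AXIAL_AXIS]
    if nz % n_out != 0:
        raise ValueError(f"axial size {nz} not divisible by {n_out}")
    g = nz // n_out
    stacked = vol.reshape(vol.shape[0], vol.shape[1], n_out, g)
    return [stacked[:, :, i, :].mean(axis=-1) for i in range(n_out)]


def overlay(pet_slice, heatmap_slice, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Fuse a grayscale PET slice with a saliency slice.

    The PET slice is rendered in grayscale; where the heatmap is non-zero
    it is blended with opacity ``alpha`` using a red-dominant colormap
    (high scores map to red).  A zero heatmap returns the pure PET image
    at any alpha.
    """
    pet = np.asarray(pet_slice, dtype=np.float64)
    heat = np.asarray(heatmap_slice, dtype=np.float64)
    if pet.shape != heat.shape:
        raise ValueError("PET and heatmap slices must have the same shape")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    lo, hi = pet.min(), pet.max()
    gray = (pet - lo) / (hi - lo) if hi > lo else np.zeros_like(pet)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    hclip = np.clip(heat, 0.0, 1.0)
    heat_rgb = colormaps[cmap](hclip)[..., :3]
    w = (alpha * (hclip > 0))[..., None]
    return (1.0 - w) * rgb + w * heat_rgb


def gradcam_gallery(pet_tensor, heatmaps, alpha: float = 0.5,
                    n_slices: int = 10):
    """Rows of fused thick slices: PET row first, one row per fold model.

    Returns a list of rows, each a list of RGB images, mirroring the
    figure layout used to present ensemble explanations (one heatmap per
    fold model per row).
    """
    pet_thick = thick_slices(pet_tensor, n_slices)
    rows = [[overlay(s, np.zeros_like(s), 0.0) for s in pet_thick]]
    for hm in heatmaps:
        h = hm.heatmap if isinstance(hm, GradCamMap) else np.asarray(hm)
        heat_thick = thick_slices(h, n_slices)
        rows.append([overlay(p, q, alpha)
                     for p, q in zip(pet_thick, heat_thick)])
    return rows
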