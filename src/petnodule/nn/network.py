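"""Sequential network container, Adam optimiser and binary cross-entropy.

The network ends in a single linear unit; the sigmoid is applied on top of
that logit.  Training uses the numerically stable logit form of binary
cross-entropy, and the optional L2 penalty is added to the loss (and its
gradient) for convolution/dense kernels only — biases are left unpenalised.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv3D, ConcatBranches, Dense, Layer, DTYPE


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z, y):
    """Mean binary cross-entropy computed from logits (stable)."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    # softplus(z) - y*z, with softplus in its overflow-safe form
    sp = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))),
                  np.log1p(np.exp(-np.abs(z))))
    return float(np.mean(sp - y * z))


class Network:
    """Ordered stack of layers mapping (N,1,40,40,40) to a logit per input."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)
        self._out_shapes = None

    # -- inference ---------------------------------------------------------
    def forward_logits(self, x, train=False):
        h = np.asarray(x, dtype=DTYPE)
        shapes = []
        for layer in self.layers:
            h = layer.forward(h, train=train)
            shapes.append(h.shape)
        self._out_shapes = shapes
        return h[:, 0] if h.ndim == 2 and h.shape[1] == 1 else h

    def predict_proba(self, x, batch_size=32):
        x = np.asarray(x, dtype=DTYPE)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(sigmoid(self.forward_logits(x[i:i + batch_size])))
        return np.concatenate(out) if out else np.empty(0)

    # -- training ----------------------------------------------------------
    def backward(self, dlogit):
        d = np.asarray(dlogit, dtype=DTYPE)
        if d.ndim == 1:
            d = d[:, None]
        for i in range(len(self.layers) - 1, -1, -1):
            d = self.layers[i].backward(d, need_dx=(i > 0))
        return d

    def backward_to(self, layer_index, dlogit):
        """Backpropagate only through layers after ``layer_index``; returns
        the gradient with respect to that layer's output."""
        d = np.asarray(dlogit, dtype=DTYPE)
        if d.ndim == 1:
            d = d[:, None]
        for layer in self.layers[:layer_index:-1]:
            d = layer.backward(d)
        return d

    # -- parameter plumbing ------------------------------------------------
    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, arr in layer.parameters():
                yield (f"layer{li}.{name}", arr)

    def gradients(self):
        for li, layer in enumerate(self.layers):
            for name, arr in layer.gradients():
                yield (f"layer{li}.{name}", arr)

    def get_weights(self):
        return [arr.copy() for _, arr in self.parameters()]

    def set_weights(self, weights):
        own = list(self.parameters())
        if len(own) != len(weights):
            raise ValueError("weight list does not match network parameters")
        for (_, arr), w in zip(own, weights):
            if arr.shape != w.shape:
                raise ValueError("weight shape mismatch")
            arr[...] = w

    def l2_penalty(self, lam, include_bias=False):
        """L2 loss term over kernels (optionally biases) of all layers."""
        if lam == 0:
            return 0.0
        total = 0.0
        for name, arr in self.parameters():
            if name.endswith(".W") or (include_bias and name.endswith(".b")):
                total += float(np.sum(arr.astype(np.float64) ** 2))
        return lam * total

    def add_l2_gradients(self, lam, include_bias=False):
        if lam == 0:
            return
        params = dict(self.parameters())
        for name, grad in self.gradients():
            if name.endswith(".W") or (include_bias and name.endswith(".b")):
                grad += DTYPE(2.0 * lam) * params[name]

    def count_parameters(self):
        return sum(arr.size for _, arr in self.parameters())

    def conv_layer_indices(self):
        """Indices of layers usable as Grad-CAM sources (spatial feature maps)."""
        return [i for i, l in enumerate(self.layers)
                if isinstance(l, (Conv3D, ConcatBranches))]

    def output_shape_of(self, layer_index):
        if self._out_shapes is None:
            raise RuntimeError("run a forward pass first")
        return self._out_shapes[layer_index]


class Adam:
    """Adam with Keras-default moments (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, network: Network, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-7):
        self.network = network
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, arr in network.parameters()}
        self.v = {name: np.zeros_like(arr) for name, arr in network.parameters()}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        params = dict(self.network.parameters())
        for name, g in self.network.gradients():
            m = self.m[name] = b1 * self.m[name] + (1 - b1) * g
            v = self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            params[name] -= DTYPE(self.lr) * mhat / (np.sqrt(vhat) + DTYPE(self.eps))
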