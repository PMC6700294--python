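"""NumPy realization of network blueprints: forward, backward, probing.

The backend contract is small: ``realize(blueprint, backend, seed)`` must
return a callable that maps a stacked 4-channel patch to a ``Cl``-channel
score map of identical spatial extent.  This module provides the package's
reference backend — a compact reverse-mode engine over five-dimensional
``(batch, channel, x, y, z)`` arrays with exactly the layer inventory the
blueprints need (dilated 3×3×1 / 1×1×3 convolutions, stride-2 in-plane
convolutions, symmetric in-plane linear upsampling, batch normalization,
PReLU, concatenation and residual addition).  It is deliberately plain
NumPy: desk-scale networks and phantoms are the target, not GPU throughput.

Conventions (mirrored one-to-one by the analytic receptive-field
calculator in :mod:`tumorcascade.blueprint`): zero 'same' padding
everywhere; a stride-2 convolution of odd kernel k is centred on even input
coordinates with padding (k-1)/2; upsampling doubles in-plane axes via
``out[2i] = in[i]``, ``out[2i+1] = (in[i] + in[i+1])/2``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .blueprint import INPUT_NODE, NetworkBlueprint, ReceptiveField
from .errors import ProbeUnderflowError, RealizationError

N_INPUT_CHANNELS = 4


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------


class _Op:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def zero_grad(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, xs, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class ConvOp(_Op):
    """Dilated, optionally strided 3D convolution with 'same' zero padding."""

    def __init__(self, in_ch, out_ch, kernel, dilation=(1, 1, 1), stride=(1, 1, 1), rng=None):
        super().__init__()
        self.kernel = tuple(kernel)
        self.dilation = tuple(dilation)
        self.stride = tuple(stride)
        fan_in = in_ch * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)
        rng = rng or np.random.default_rng()
        self.params["W"] = (rng.standard_normal((out_ch, in_ch) + self.kernel) * scale).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.zero_grad()

    def _geometry(self, shape):
        pads, outs = [], []
        for ax in range(3):
            k, d, s = self.kernel[ax], self.dilation[ax], self.stride[ax]
            p = d * (k - 1) // 2
            o = (shape[ax] + 2 * p - d * (k - 1) - 1) // s + 1
            pads.append(p)
            outs.append(o)
        return tuple(pads), tuple(outs)

    def _tap_slices(self, tap, outs):
        sl = [slice(None), slice(None)]
        for ax in range(3):
            start = tap[ax] * self.dilation[ax]
            sl.append(slice(start, start + self.stride[ax] * (outs[ax] - 1) + 1, self.stride[ax]))
        return tuple(sl)

    def forward(self, xs, training):
        (x,) = xs
        pads, outs = self._geometry(x.shape[2:])
        x_pad = np.pad(x, ((0, 0), (0, 0)) + tuple((p, p) for p in pads))
        self._cache = (x_pad, x.shape, pads, outs)
        W, b = self.params["W"], self.params["b"]
        out = np.empty((x.shape[0], W.shape[0]) + outs, dtype=x.dtype)
        out[:] = b[None, :, None, None, None]
        for tap in np.ndindex(*self.kernel):
            view = x_pad[self._tap_slices(tap, outs)]
            out += np.einsum("oc,bcxyz->boxyz", W[(slice(None), slice(None)) + tap], view,
                             optimize=True)
        return out

    def backward(self, grad):
        x_pad, x_shape, pads, outs = self._cache
        W = self.params["W"]
        self.grads["b"] += grad.sum(axis=(0, 2, 3, 4), dtype=W.dtype)
        dx_pad = np.zeros_like(x_pad)
        for tap in np.ndindex(*self.kernel):
            sl = self._tap_slices(tap, outs)
            view = x_pad[sl]
            widx = (slice(None), slice(None)) + tap
            self.grads["W"][widx] += np.einsum("boxyz,bcxyz->oc", grad, view, optimize=True)
            dx_pad[sl] += np.einsum("oc,boxyz->bcxyz", W[widx], grad, optimize=True)
        core = tuple(slice(p, p + n) for p, n in zip(pads, x_shape[2:]))
        return [dx_pad[(slice(None), slice(None)) + core]]


class BatchNormOp(_Op):
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.zero_grad()

    def forward(self, xs, training):
        (x,) = xs
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        self._cache = (xhat, inv, training, x.shape)
        g, b = self.params["gamma"], self.params["beta"]
        return g[None, :, None, None, None] * xhat + b[None, :, None, None, None]

    def backward(self, grad):
        xhat, inv, training, shape = self._cache
        axes = (0, 2, 3, 4)
        g = self.params["gamma"][None, :, None, None, None]
        self.grads["gamma"] += (grad * xhat).sum(axis=axes)
        self.grads["beta"] += grad.sum(axis=axes)
        dxhat = grad * g
        if not training:
            return [dxhat * inv[None, :, None, None, None]]
        n = shape[0] * shape[2] * shape[3] * shape[4]
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        dx = (dxhat - s1 / n - xhat * s2 / n) * inv[None, :, None, None, None]
        return [dx]


class PReLUOp(_Op):
    def __init__(self, channels, init_slope=0.25):
        super().__init__()
        self.params["a"] = np.full(channels, init_slope, dtype=np.float32)
        self.zero_grad()

    def forward(self, xs, training):
        (x,) = xs
        a = self.params["a"][None, :, None, None, None]
        self._cache = x
        return np.where(x > 0, x, a * x)

    def backward(self, grad):
        x = self._cache
        a = self.params["a"][None, :, None, None, None]
        self.grads["a"] += (grad * np.where(x > 0, 0.0, x)).sum(axis=(0, 2, 3, 4))
        return [grad * np.where(x > 0, 1.0, a)]


def _up1(x):
    """Symmetric ×2 linear upsampling along the last axis."""
    n = x.shape[-1]
    out = np.empty(x.shape[:-1] + (2 * n,), dtype=x.dtype)
    out[..., 0::2] = x
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out[..., 1::2] = 0.5 * (x + nxt)
    return out


def _up1_adjoint(g):
    go = g[..., 1::2]
    dx = g[..., 0::2] + 0.5 * go
    dx[..., 1:] += 0.5 * go[..., :-1]
    dx[..., -1] += 0.5 * go[..., -1]
    return dx


class UpsampleOp(_Op):
    """In-plane ×2 upsampling (axes x and y of (B, C, x, y, z))."""

    def forward(self, xs, training):
        (x,) = xs
        out = np.moveaxis(_up1(np.moveaxis(x, 2, -1)), -1, 2)
        out = np.moveaxis(_up1(np.moveaxis(out, 3, -1)), -1, 3)
        return out

    def backward(self, grad):
        g = np.moveaxis(_up1_adjoint(np.moveaxis(grad, 3, -1)), -1, 3)
        g = np.moveaxis(_up1_adjoint(np.moveaxis(g, 2, -1)), -1, 2)
        return [g]


class ConcatOp(_Op):
    def forward(self, xs, training):
        self._splits = [x.shape[1] for x in xs]
        return np.concatenate(xs, axis=1)

    def backward(self, grad):
        out, start = [], 0
        for c in self._splits:
            out.append(grad[:, start:start + c])
            start += c
        return out


class AddOp(_Op):
    def forward(self, xs, training):
        a, b = xs
        return a + b

    def backward(self, grad):
        return [grad, grad]


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    name: str
    op: _Op
    inputs: tuple


class NumpyNetwork:
    """A realized blueprint: callable predictor with reverse-mode gradients.

    Input spatial extents are padded on the high side to a multiple of the
    blueprint's total in-plane stride and the output is cropped back, so the
    realize contract (output spatial shape equals input spatial shape,
    ``Cl`` channels) holds for any input size.
    """

    def __init__(self, blueprint: NetworkBlueprint, seed: int = 0):
        self.blueprint = blueprint
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.nodes = []
        channels = {INPUT_NODE: N_INPUT_CHANNELS}
        for layer in blueprint.layers:
            in_ch = channels[layer.inputs[0]]
            kind = layer.kind
            if kind in ("intra_conv", "inter_conv", "downsample2d", "prediction_head"):
                if kind == "intra_conv":
                    kernel, dil, stride = (layer.kernel, layer.kernel, 1), (layer.dilation,) * 2 + (1,), (1, 1, 1)
                elif kind == "inter_conv":
                    kernel, dil, stride = (1, 1, 3), (1, 1, 1), (1, 1, 1)
                elif kind == "downsample2d":
                    kernel, dil, stride = (layer.kernel, layer.kernel, 1), (1, 1, 1), (2, 2, 1)
                else:
                    kernel, dil, stride = (3, 3, 1), (1, 1, 1), (1, 1, 1)
                conv = ConvOp(in_ch, layer.out_channels, kernel, dil, stride, rng=rng)
                self.nodes.append(_Node(layer.name + "/conv", conv, layer.inputs))
                prev = layer.name + "/conv"
                if kind != "prediction_head":
                    # realization contract: conv -> batch norm -> PReLU
                    self.nodes.append(_Node(layer.name + "/bn", BatchNormOp(layer.out_channels), (prev,)))
                    self.nodes.append(_Node(layer.name + "/prelu", PReLUOp(layer.out_channels),
                                            (layer.name + "/bn",)))
                    prev = layer.name + "/prelu"
                self._alias = getattr(self, "_alias", {})
                self._alias[layer.name] = prev
            elif kind == "upsample2d":
                self.nodes.append(_Node(layer.name, UpsampleOp(), layer.inputs))
                self._alias[layer.name] = layer.name
            elif kind == "concat":
                self.nodes.append(_Node(layer.name, ConcatOp(), layer.inputs))
                self._alias[layer.name] = layer.name
            elif kind == "residual_add":
                self.nodes.append(_Node(layer.name, AddOp(), layer.inputs))
                self._alias[layer.name] = layer.name
            channels[layer.name] = layer.out_channels
        # resolve aliases (blueprint names -> realized sub-node names)
        for node in self.nodes:
            node.inputs = tuple(
                self._alias.get(src, src) if src != INPUT_NODE else INPUT_NODE
                for src in node.inputs
            )
        self.output_name = self._alias[blueprint.output_layer.name]

    # -- execution ---------------------------------------------------------

    def _pad_to_stride(self, x):
        s = self.blueprint.inplane_stride
        px = (-x.shape[2]) % s
        py = (-x.shape[3]) % s
        if px or py:
            x = np.pad(x, ((0, 0), (0, 0), (0, px), (0, py), (0, 0)))
        return x

    def forward(self, x, training: bool = False):
        """Scores of shape (B, Cl, X, Y, Z) for input (B, 4, X, Y, Z).

        A 4D input (4, X, Y, Z) is promoted to a singleton batch and the
        batch axis is dropped again on return.
        """
        squeeze = x.ndim == 4
        if squeeze:
            x = x[None]
        if x.shape[1] != N_INPUT_CHANNELS:
            raise RealizationError(f"expected {N_INPUT_CHANNELS} input channels, got {x.shape[1]}")
        spatial = x.shape[2:]
        xp = self._pad_to_stride(np.ascontiguousarray(x))
        values = {INPUT_NODE: xp}
        for node in self.nodes:
            values[node.name] = node.op.forward([values[s] for s in node.inputs], training)
        out = values[self.output_name][:, :, :spatial[0], :spatial[1], :spatial[2]]
        if out.shape[2:] != spatial or out.shape[1] != self.blueprint.Cl:
            raise RealizationError(
                f"realization contract violated: output {out.shape[1:]} for input {x.shape[1:]}"
            )
        self._fwd_spatial = spatial
        self._fwd_padded = values[INPUT_NODE].shape[2:]
        return out[0] if squeeze else out

    def predict_proba(self, x):
        """Softmax class probabilities, same layout as :meth:`forward`."""
        scores = self.forward(np.asarray(x, dtype=np.float32), training=False)
        return softmax_channels(scores, axis=scores.ndim - 4)

    __call__ = predict_proba

    def backward(self, dout):
        """Propagate d(loss)/d(scores) back to the input; accumulates grads."""
        if dout.ndim == 4:
            dout = dout[None]
        spatial = self._fwd_spatial
        padded = self._fwd_padded
        if dout.shape[2:] != spatial:
            raise RealizationError("backward called with mismatched gradient shape")
        full = np.zeros(dout.shape[:2] + padded, dtype=dout.dtype)
        full[:, :, :spatial[0], :spatial[1], :spatial[2]] = dout
        grads = {self.output_name: full}
        for node in reversed(self.nodes):
            g = grads.pop(node.name, None)
            if g is None:
                continue
            for src, gin in zip(node.inputs, node.op.backward(g)):
                if src in grads:
                    grads[src] = grads[src] + gin
                else:
                    grads[src] = gin
        gin = grads[INPUT_NODE]
        return gin[:, :, :spatial[0], :spatial[1], :spatial[2]]

    # -- parameter access --------------------------------------------------

    def parameters(self):
        return {f"{n.name}/{k}": v for n in self.nodes for k, v in n.op.params.items()}

    def gradients(self):
        return {f"{n.name}/{k}": v for n in self.nodes for k, v in n.op.grads.items()}

    def zero_grad(self):
        for n in self.nodes:
            n.op.zero_grad()

    def state_dict(self):
        state = {k: v.copy() for k, v in self.parameters().items()}
        for n in self.nodes:
            if isinstance(n.op, BatchNormOp):
                state[f"{n.name}/running_mean"] = n.op.running_mean.copy()
                state[f"{n.name}/running_var"] = n.op.running_var.copy()
        return state

    def load_state_dict(self, state):
        params = self.parameters()
        for k, v in state.items():
            if k.endswith("/running_mean") or k.endswith("/running_var"):
                node_name, attr = k.rsplit("/", 1)
                for n in self.nodes:
                    if n.name == node_name:
                        setattr(n.op, attr, np.asarray(v, dtype=np.float32).copy())
            elif k in params:
                params[k][...] = v
            else:
                raise RealizationError(f"unknown parameter {k!r} in state dict")

    # -- probing -----------------------------------------------------------

    def linearized(self):
        """A positive-sensitivity, linear-regime copy for receptive-field probing.

        Convolution weights become their magnitudes (normalized per output
        channel so activations stay O(1) at any depth), biases vanish, batch
        norm is frozen to the identity and PReLU slopes are set to 1; the
        copy is exactly linear with nonnegative coefficients, so the support
        of the input gradient equals the receptive field.
        """
        lin = copy.deepcopy(self)
        for node in lin.nodes:
            op = node.op
            if isinstance(op, ConvOp):
                W = np.abs(op.params["W"]).astype(np.float64) + 1e-3
                norm = W.sum(axis=(1, 2, 3, 4), keepdims=True)
                op.params["W"] = W / norm
                op.params["b"] = np.zeros_like(op.params["b"], dtype=np.float64)
            elif isinstance(op, BatchNormOp):
                op.params["gamma"] = np.ones_like(op.params["gamma"], dtype=np.float64)
                op.params["beta"] = np.zeros_like(op.params["beta"], dtype=np.float64)
                op.running_mean = np.zeros_like(op.running_mean, dtype=np.float64)
                op.running_var = np.ones_like(op.running_var, dtype=np.float64) - 1e-5
            elif isinstance(op, PReLUOp):
                op.params["a"] = np.ones_like(op.params["a"], dtype=np.float64)
            op.zero_grad()
        return lin


def softmax_channels(scores, axis=1):
    shifted = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


class NumpyBackend:
    """Default (and reference) backend satisfying the realization contract."""

    def realize(self, blueprint: NetworkBlueprint, seed: int = 0) -> NumpyNetwork:
        return NumpyNetwork(blueprint, seed=seed)


def realize(blueprint: NetworkBlueprint, backend=None, seed: int = 0) -> NumpyNetwork:
    """Turn a blueprint into a callable predictor (deterministic given seed)."""
    backend = backend or NumpyBackend()
    return backend.realize(blueprint, seed=seed)


def probe_receptive_field(network: NumpyNetwork, input_extent) -> ReceptiveField:
    """Empirical receptive field by sensitivity probing of a central voxel.

    The network is linearized (see :meth:`NumpyNetwork.linearized`), a unit
    gradient is injected at a stride-aligned central output voxel, and the
    support of the resulting input gradient is measured.  If the support
    touches the input boundary the input was smaller than the true
    receptive field and a :class:`ProbeUnderflowError` is raised.
    """
    extent = tuple(int(e) for e in input_extent)
    lin = network.linearized()
    x = np.ones((1, N_INPUT_CHANNELS) + extent, dtype=np.float64)
    scores = lin.forward(x, training=False)
    s = network.blueprint.inplane_stride
    center = (extent[0] // 2 // s * s, extent[1] // 2 // s * s, extent[2] // 2)
    dout = np.zeros_like(scores)
    dout[0, 0, center[0], center[1], center[2]] = 1.0
    grad = lin.backward(dout)
    # the linearized network has strictly positive coefficients, so any
    # influence is strictly positive in float64 — no tolerance needed
    support = grad.sum(axis=(0, 1)) > 0.0
    extents = []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        hit = np.where(support.any(axis=other))[0]
        if hit.size == 0:
            raise ProbeUnderflowError("no input sensitivity found")
        lo, hi = int(hit[0]), int(hit[-1])
        if lo == 0 or hi == extent[ax] - 1:
            raise ProbeUnderflowError(
                f"receptive field reaches the input boundary along axis {ax}; "
                f"increase the probe extent (got {extent})"
            )
        extents.append(hi - lo + 1)
    return ReceptiveField(extents=tuple(extents))
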