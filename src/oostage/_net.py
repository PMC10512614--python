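"""Compact NumPy CNN engine: static layer graphs, backprop, Adam.

The staging networks are small enough that an im2col-based NumPy
implementation trains them comfortably on one CPU, and it keeps the whole
pipeline dependency-light and bit-reproducible.  A network is described by a
list of :class:`LayerSpec` nodes (a DAG in topological order: each node names
its inputs), executed by :class:`Network` with hand-written forward/backward
passes.  Supported kinds:

``input, conv, relu, maxpool, concat, gap (global average pool), fc,
upsample (nearest-neighbor), dropout (active only when a generator is
passed to forward)``

Activations use NCHW layout.  Convolution/fc weights are He-initialised from
a seeded generator; pooling uses floor-mode output sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["LayerSpec", "propagate_shapes", "Network", "Adam", "softmax", "cross_entropy"]


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str
    inputs: tuple[str, ...] = ()
    kernel: int = 1
    stride: int = 1
    padding: int = 0
    filters: int = 0          # conv output channels / fc output units
    factor: int = 2           # upsample factor
    rate: float = 0.0         # dropout rate
    out_shape: tuple[int, ...] = ()  # (C, H, W), filled by propagate_shapes


def _conv_out(side: int, kernel: int, stride: int, padding: int) -> int:
    out = (side + 2 * padding - kernel) // stride + 1
    if out < 1:
        raise ValueError(f"layer output side collapsed to {out}")
    return out


def propagate_shapes(specs: list[LayerSpec], input_shape: tuple[int, int, int]) -> list[LayerSpec]:
    """Fill every spec's ``out_shape`` from the (C, H, W) input shape."""
    shapes: dict[str, tuple[int, ...]] = {}
    out = []
    for s in specs:
        if s.kind == "input":
            shape = tuple(input_shape)
        else:
            ins = [shapes[n] for n in s.inputs]
            c, h, w = ins[0] if len(ins[0]) == 3 else (ins[0][0], 1, 1)
            if s.kind == "conv":
                shape = (s.filters, _conv_out(h, s.kernel, s.stride, s.padding),
                         _conv_out(w, s.kernel, s.stride, s.padding))
            elif s.kind == "maxpool":
                shape = (c, _conv_out(h, s.kernel, s.stride, s.padding),
                         _conv_out(w, s.kernel, s.stride, s.padding))
            elif s.kind == "relu":
                shape = ins[0]
            elif s.kind == "concat":
                if any(i[1:] != ins[0][1:] for i in ins):
                    raise ValueError(f"concat inputs of {s.name} disagree in spatial size")
                shape = (sum(i[0] for i in ins), h, w)
            elif s.kind == "gap":
                shape = (c,)
            elif s.kind == "fc":
                shape = (s.filters,)
            elif s.kind == "upsample":
                shape = (c, h * s.factor, w * s.factor)
            elif s.kind == "dropout":
                shape = ins[0]
            else:
                raise ValueError(f"unknown layer kind {s.kind!r}")
        shapes[s.name] = shape
        out.append(replace(s, out_shape=shape))
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows of (N, K) logits; returns (loss, dlogits).

    Optional per-class weights rescale each row's contribution (weighted mean),
    used for heavily imbalanced per-pixel targets.
    """
    p = softmax(logits)
    n = logits.shape[0]
    nll = -np.log(p[np.arange(n), labels] + 1e-12)
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    if class_weights is None:
        return float(nll.mean()), dlogits / n
    w = np.asarray(class_weights, dtype=np.float64)[labels]
    wsum = w.sum()
    return float((w * nll).sum() / wsum), dlogits * (w / wsum)[:, None]


def _conv_forward(x, W, b, stride, padding):
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    k = W.shape[2]
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.tensordot(win, W, axes=([1, 4, 5], [1, 2, 3]))  # N,Ho,Wo,F
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + b[None, :, None, None]
    return out, (x, win)


def _conv_backward(dout, cache, W, stride, padding, in_shape):
    x_pad, win = cache
    dW = np.tensordot(dout, win, axes=([0, 2, 3], [0, 2, 3]))  # F,C,k,k
    db = dout.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(x_pad)
    k = W.shape[2]
    ho, wo = dout.shape[2], dout.shape[3]
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += np.einsum(
                "nfhw,fc->nchw", dout, W[:, :, i, j], optimize=True
            )
    if padding:
        dxp = dxp[:, :, padding:-padding, padding:-padding]
    return dxp, dW, db


class Network:
    """Executes a LayerSpec DAG; holds parameters and supports backprop."""

    def __init__(self, specs: list[LayerSpec], seed: int = 0):
        if specs[0].kind != "input":
            raise ValueError("first layer must be the input")
        self.specs = specs
        self.by_name = {s.name: s for s in specs}
        rng = np.random.default_rng(seed)
        self.params: dict[str, list[np.ndarray]] = {}
        shapes = {s.name: s.out_shape for s in specs}
        for s in specs:
            if s.kind == "conv":
                cin = shapes[s.inputs[0]][0]
                std = np.sqrt(2.0 / (cin * s.kernel * s.kernel))
                # small positive bias keeps ReLUs alive on sparse binary inputs
                self.params[s.name] = [
                    rng.normal(0, std, size=(s.filters, cin, s.kernel, s.kernel)).astype(np.float64),
                    np.full(s.filters, 0.01),
                ]
            elif s.kind == "fc":
                din = int(np.prod(shapes[s.inputs[0]]))
                std = np.sqrt(2.0 / din)
                self.params[s.name] = [
                    rng.normal(0, std, size=(din, s.filters)).astype(np.float64),
                    np.zeros(s.filters),
                ]

    # --- state -----------------------------------------------------------
    def get_state(self) -> dict[str, list[np.ndarray]]:
        return {k: [w.copy() for w in v] for k, v in self.params.items()}

    def set_state(self, state: dict[str, list[np.ndarray]]) -> None:
        for k, v in state.items():
            self.params[k] = [w.copy() for w in v]

    def param_items(self):
        for name in sorted(self.params):
            for i, w in enumerate(self.params[name]):
                yield (name, i), w

    # --- execution --------------------------------------------------------
    def forward(self, x: np.ndarray, keep: bool = False,
                dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        acts: dict[str, np.ndarray] = {}
        caches: dict[str, object] = {}
        for s in self.specs:
            if s.kind == "input":
                acts[s.name] = x
            elif s.kind == "conv":
                W, b = self.params[s.name]
                acts[s.name], caches[s.name] = _conv_forward(acts[s.inputs[0]], W, b, s.stride, s.padding)
            elif s.kind == "relu":
                acts[s.name] = np.maximum(acts[s.inputs[0]], 0.0)
            elif s.kind == "maxpool":
                xin = acts[s.inputs[0]]
                win = sliding_window_view(xin, (s.kernel, s.kernel), axis=(2, 3))[:, :, ::s.stride, ::s.stride]
                flat = win.reshape(*win.shape[:4], -1)
                am = flat.argmax(axis=-1)
                acts[s.name] = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]
                caches[s.name] = (xin.shape, am)
            elif s.kind == "concat":
                acts[s.name] = np.concatenate([acts[n] for n in s.inputs], axis=1)
            elif s.kind == "gap":
                acts[s.name] = acts[s.inputs[0]].mean(axis=(2, 3))
            elif s.kind == "fc":
                W, b = self.params[s.name]
                xin = acts[s.inputs[0]].reshape(acts[s.inputs[0]].shape[0], -1)
                caches[s.name] = xin
                acts[s.name] = xin @ W + b
            elif s.kind == "upsample":
                acts[s.name] = np.repeat(np.repeat(acts[s.inputs[0]], s.factor, axis=2), s.factor, axis=3)
            elif s.kind == "dropout":
                if dropout_rng is None or s.rate == 0:
                    acts[s.name] = acts[s.inputs[0]]
                    caches[s.name] = None
                else:
                    mask = (dropout_rng.uniform(size=acts[s.inputs[0]].shape) >= s.rate) / (1 - s.rate)
                    acts[s.name] = acts[s.inputs[0]] * mask
                    caches[s.name] = mask
        if keep:
            self._acts, self._caches = acts, caches
        return acts[self.specs[-1].name]

    def backward(self, dout: np.ndarray) -> dict[str, list[np.ndarray]]:
        """Backprop from the last layer; requires a prior forward(keep=True)."""
        acts, caches = self._acts, self._caches
        dacts: dict[str, np.ndarray] = {self.specs[-1].name: dout}
        grads: dict[str, list[np.ndarray]] = {}
        for s in reversed(self.specs):
            if s.name not in dacts or s.kind == "input":
                continue
            d = dacts.pop(s.name)
            if s.kind == "conv":
                W, _ = self.params[s.name]
                dx, dW, db = _conv_backward(d, caches[s.name], W, s.stride, s.padding,
                                            acts[s.inputs[0]].shape)
                grads[s.name] = [dW, db]
            elif s.kind == "relu":
                dx = d * (acts[s.name] > 0)
            elif s.kind == "maxpool":
                in_shape, am = caches[s.name]
                dx = np.zeros(in_shape)
                n, c, ho, wo = am.shape
                rows = (np.arange(ho)[None, None, :, None] * s.stride) + am // s.kernel
                cols = (np.arange(wo)[None, None, None, :] * s.stride) + am % s.kernel
                ni = np.arange(n)[:, None, None, None]
                ci = np.arange(c)[None, :, None, None]
                np.add.at(dx, (ni, ci, rows, cols), d)
            elif s.kind == "concat":
                ofs = 0
                for name in s.inputs:
                    cn = acts[name].shape[1]
                    piece = d[:, ofs : ofs + cn]
                    dacts[name] = dacts.get(name, 0) + piece
                    ofs += cn
                continue
            elif s.kind == "gap":
                _, c, h, w = acts[s.inputs[0]].shape
                dx = np.broadcast_to(d[:, :, None, None], acts[s.inputs[0]].shape) / (h * w)
            elif s.kind == "fc":
                W, _ = self.params[s.name]
                xin = caches[s.name]
                grads[s.name] = [xin.T @ d, d.sum(axis=0)]
                dx = (d @ W.T).reshape(acts[s.inputs[0]].shape)
            elif s.kind == "upsample":
                n, c, h, w = acts[s.inputs[0]].shape
                dx = d.reshape(n, c, h, s.factor, w, s.factor).sum(axis=(3, 5))
            elif s.kind == "dropout":
                mask = caches[s.name]
                dx = d if mask is None else d * mask
            else:  # pragma: no cover
                raise ValueError(s.kind)
            dacts[s.inputs[0]] = dacts.get(s.inputs[0], 0) + dx
        return grads


class Adam:
    """Adam optimizer over a network's parameter dictionary."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: [np.zeros_like(w) for w in v] for k, v in net.params.items()}
        self.v = {k: [np.zeros_like(w) for w in v] for k, v in net.params.items()}

    def step(self, grads: dict[str, list[np.ndarray]]) -> None:
        self.t += 1
        for name, gs in grads.items():
            for i, g in enumerate(gs):
                m = self.m[name][i] = self.b1 * self.m[name][i] + (1 - self.b1) * g
                v = self.v[name][i] = self.b2 * self.v[name][i] + (1 - self.b2) * g * g
                mh = m / (1 - self.b1**self.t)
                vh = v / (1 - self.b2**self.t)
                self.net.params[name][i] -= self.lr * mh / (np.sqrt(vh) + self.eps)
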