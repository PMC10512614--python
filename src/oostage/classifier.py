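"""SqueezeNet-inspired maturity classifier family, its training, and FLOPs.

The classifier topology is fixed; only the per-layer 2-D convolution filter
counts vary, encoded as a 6-gene *chromosome* (conv1, conv2, fire squeeze,
fire 3×3 branch, fire 1×1 branch, conv6/conv7), every gene even and in
[2, 128].  The network is

    conv 3×3/s2 → relu → maxpool 3×3/s2 → conv 1×1 → relu → maxpool 3×3/s2
    → n_inception × [squeeze 1×1 → relu → (3×3 pad 1 ‖ 1×1) → relu
                     → depth-concat → maxpool 3×3/s2]
    → conv 1×1 → relu → conv 1×1 → relu → global-avg-pool → fc(3) → softmax

with all inception blocks sharing the chromosome's fire genes.  The 3×3 fire
branch is padded so the two branches concatenate; an optional dropout
(rate 0.5) before conv6 is off by default.  Training uses cross-entropy with
Adam on class-balanced batches redrawn each epoch; per-epoch snapshots record
validation accuracy and the best snapshot is the validation argmax (earliest
epoch on ties).

FLOPs are counted analytically per layer as output elements × kernel area ×
input channels multiply-accumulates (MAC=1 by default; MAC=2 selectable),
which makes the count exact for this all-conv/fc family and monotone in every
filter count and in the input side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._net import Adam, LayerSpec, Network, cross_entropy, propagate_shapes, softmax
from .dataio import InputTensor
from .sampling import balanced_batch, epoch_reseed

__all__ = [
    "Chromosome",
    "ArchitectureSpec",
    "TrainConfig",
    "Snapshot",
    "build_architecture",
    "count_flops",
    "train_classifier",
    "select_snapshot",
    "classify",
    "predict_labels",
    "save_snapshot",
    "load_snapshot",
]

FILTER_BOUNDS = (2, 128)
N_GENES = 6
REFERENCE_CHROMOSOME = (32, 16, 8, 28, 28, 4)  # the GA-refined reference structure


@dataclass(frozen=True)
class Chromosome:
    """Six even filter counts in [2, 128], one per tunable convolution."""

    filters: tuple[int, ...]

    def __post_init__(self):
        if len(self.filters) != N_GENES:
            raise ValueError(f"chromosome must have {N_GENES} genes, got {len(self.filters)}")
        lo, hi = FILTER_BOUNDS
        for f in self.filters:
            if f % 2 or not lo <= f <= hi:
                raise ValueError(f"gene {f} must be even and within [{lo}, {hi}]")

    @property
    def total(self) -> int:
        return sum(self.filters)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Shape-propagated layer graph for one chromosome/input configuration."""

    layers: tuple[LayerSpec, ...]
    chromosome: Chromosome
    n_channels: int
    n_inception: int
    input_side: int
    dropout: float = 0.0

    def layer(self, name: str) -> LayerSpec:
        return next(s for s in self.layers if s.name == name)


def build_architecture(
    chromosome: Chromosome | tuple[int, ...],
    n_channels: int = 2,
    n_inception: int = 1,
    input_side: int = 590,
    dropout: float = 0.0,
) -> ArchitectureSpec:
    """Instantiate the classifier layer graph for one chromosome."""
    if not isinstance(chromosome, Chromosome):
        chromosome = Chromosome(tuple(chromosome))
    if not 0 <= n_inception <= 4:
        raise ValueError("n_inception must be in [0, 4]")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    f1, f2, f_sq, f_e3, f_e1, f6 = chromosome.filters
    specs = [
        LayerSpec("input", "input"),
        LayerSpec("conv1", "conv", ("input",), kernel=3, stride=2, filters=f1),
        LayerSpec("relu_conv1", "relu", ("conv1",)),
        LayerSpec("pool1", "maxpool", ("relu_conv1",), kernel=3, stride=2),
        LayerSpec("conv2", "conv", ("pool1",), kernel=1, filters=f2),
        LayerSpec("relu_conv2", "relu", ("conv2",)),
        LayerSpec("pool2", "maxpool", ("relu_conv2",), kernel=3, stride=2),
    ]
    prev = "pool2"
    for b in range(1, n_inception + 1):
        specs += [
            LayerSpec(f"squeeze{b}", "conv", (prev,), kernel=1, filters=f_sq),
            LayerSpec(f"relu_squeeze{b}", "relu", (f"squeeze{b}",)),
            LayerSpec(f"fire{b}_3x3", "conv", (f"relu_squeeze{b}",), kernel=3, padding=1, filters=f_e3),
            LayerSpec(f"relu_fire{b}_3x3", "relu", (f"fire{b}_3x3",)),
            LayerSpec(f"fire{b}_1x1", "conv", (f"relu_squeeze{b}",), kernel=1, filters=f_e1),
            LayerSpec(f"relu_fire{b}_1x1", "relu", (f"fire{b}_1x1",)),
            LayerSpec(f"concat{b}", "concat", (f"relu_fire{b}_3x3", f"relu_fire{b}_1x1")),
            LayerSpec(f"pool_concat{b}", "maxpool", (f"concat{b}",), kernel=3, stride=2),
        ]
        prev = f"pool_concat{b}"
    if dropout > 0:
        specs.append(LayerSpec("drop6", "dropout", (prev,), rate=dropout))
        prev = "drop6"
    specs += [
        LayerSpec("conv6", "conv", (prev,), kernel=1, filters=f6),
        LayerSpec("relu_conv6", "relu", ("conv6",)),
        LayerSpec("conv7", "conv", ("relu_conv6",), kernel=1, filters=f6),
        LayerSpec("relu_conv7", "relu", ("conv7",)),
        LayerSpec("gap", "gap", ("relu_conv7",)),
        LayerSpec("fc", "fc", ("gap",), filters=3),
    ]
    layers = tuple(propagate_shapes(specs, (n_channels, input_side, input_side)))
    return ArchitectureSpec(layers, chromosome, n_channels, n_inception, input_side, dropout)


def count_flops(spec: ArchitectureSpec, mac: int = 1) -> int:
    """Analytic FLOPs of one forward pass over the conv/fc layers.

    Each convolution contributes output elements × kh × kw × input channels
    multiply-accumulate operations (a MAC counts as ``mac`` FLOPs); a fully
    connected layer contributes in × out MACs.
    """
    if mac not in (1, 2):
        raise ValueError("mac must be 1 or 2")
    shapes = {s.name: s.out_shape for s in spec.layers}
    total = 0
    for s in spec.layers:
        if s.kind == "conv":
            cin = shapes[s.inputs[0]][0]
            c, h, w = s.out_shape
            total += c * h * w * s.kernel * s.kernel * cin
        elif s.kind == "fc":
            total += int(np.prod(shapes[s.inputs[0]])) * s.filters
    return total * mac


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 84
    steps_per_epoch: int | None = None  # default: ceil(n_train / batch_size)
    seed: int = 0
    metric: str = "val_accuracy"  # snapshot-selection metric

    def validate(self) -> "TrainConfig":
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        return self


@dataclass
class Snapshot:
    """Network state after one training epoch, with its validation score."""

    epoch: int
    state: dict
    metrics: dict[str, float]
    arch: ArchitectureSpec


def _to_nchw(tensors: list[InputTensor]) -> np.ndarray:
    return np.stack([t.data.transpose(2, 0, 1) for t in tensors]).astype(np.float64)


def _forward_batched(net: Network, X: np.ndarray, chunk: int = 32) -> np.ndarray:
    outs = [net.forward(X[i : i + chunk]) for i in range(0, len(X), chunk)]
    return np.concatenate(outs)


def train_classifier(dataset, split: dict[str, list[str]], arch: ArchitectureSpec,
                     cfg: TrainConfig) -> list[Snapshot]:
    """Train on one SRRS repetition; returns one snapshot per epoch.

    ``dataset`` provides ``labels`` (id → class), ``n_variants(id)`` and
    ``load(id, variant) → InputTensor`` (e.g. an augmentation cache or an
    in-memory tensor store).  Training draws class-balanced batches, reseeded
    every epoch, picking a random augmentation variant per draw; validation
    always uses variant 0.  Deterministic under ``cfg.seed``.
    """
    cfg.validate()
    missing = [i for i in split["train"] + split["val"] if i not in dataset.labels]
    if missing:
        raise ValueError(f"dataset is missing records: {missing[:5]}")
    train_by_class: dict[str, list[str]] = {}
    for rid in split["train"]:
        train_by_class.setdefault(dataset.labels[rid], []).append(rid)

    from .records import LABELS

    val_ids = list(split["val"])
    X_val = _to_nchw([dataset.load(i, 0) for i in val_ids]) if val_ids else None
    y_val = np.array([LABELS.index(dataset.labels[i]) for i in val_ids])

    net = Network(list(arch.layers), seed=cfg.seed)
    opt = Adam(net, lr=cfg.learning_rate)
    steps = cfg.steps_per_epoch or max(1, math.ceil(len(split["train"]) / cfg.batch_size))
    snapshots: list[Snapshot] = []
    for epoch in range(1, cfg.epochs + 1):
        eseed = epoch_reseed(epoch, cfg.seed)
        losses = []
        for step in range(steps):
            sseed = epoch_reseed(step, eseed)
            ids = balanced_batch(train_by_class, cfg.batch_size, seed=sseed)
            rng = np.random.default_rng(sseed)
            tensors = [dataset.load(i, int(rng.integers(dataset.n_variants(i)))) for i in ids]
            X = _to_nchw(tensors)
            y = np.array([LABELS.index(dataset.labels[i]) for i in ids])
            logits = net.forward(X, keep=True, dropout_rng=rng if arch.dropout else None)
            loss, dlogits = cross_entropy(logits, y)
            opt.step(net.backward(dlogits))
            losses.append(loss)
        metrics = {"train_loss": float(np.mean(losses))}
        if X_val is not None:
            pred = _forward_batched(net, X_val).argmax(axis=1)
            metrics["val_accuracy"] = float(np.mean(pred == y_val))
        snapshots.append(Snapshot(epoch=epoch, state=net.get_state(), metrics=metrics, arch=arch))
    return snapshots


def select_snapshot(snapshots: list[Snapshot], metric: str = "val_accuracy") -> Snapshot:
    """The snapshot maximizing the validation metric; earliest epoch on ties."""
    if not snapshots:
        raise ValueError("no snapshots to select from")
    best = snapshots[0]
    for s in snapshots[1:]:
        if s.metrics.get(metric, -np.inf) > best.metrics.get(metric, -np.inf):
            best = s
    return best


def classify(tensor: InputTensor, snapshot: Snapshot) -> tuple[str, np.ndarray]:
    """Class probabilities for one input tensor: (predicted label, p[MI,MII,PI])."""
    from .records import LABELS

    expect = (snapshot.arch.n_channels, snapshot.arch.input_side, snapshot.arch.input_side)
    x = tensor.data.transpose(2, 0, 1).astype(np.float64)
    if x.shape != expect:
        raise ValueError(f"tensor shape {x.shape} does not match the snapshot input {expect}")
    net = Network(list(snapshot.arch.layers), seed=0)
    net.set_state(snapshot.state)
    probs = softmax(net.forward(x[None]))[0]
    return LABELS[int(probs.argmax())], probs


def predict_labels(dataset, ids: list[str], snapshot: Snapshot, variant: int = 0) -> list[str]:
    """Predicted labels for a list of record ids (variant 0 by default)."""
    from .records import LABELS

    net = Network(list(snapshot.arch.layers), seed=0)
    net.set_state(snapshot.state)
    X = _to_nchw([dataset.load(i, variant) for i in ids])
    pred = _forward_batched(net, X).argmax(axis=1)
    return [LABELS[int(p)] for p in pred]


def save_snapshot(snapshot: Snapshot, path: str | Path) -> None:
    """Portable container: .npz weights + JSON sidecar with the architecture."""
    path = Path(path)
    arrays = {}
    for name, ws in snapshot.state.items():
        for i, w in enumerate(ws):
            arrays[f"{name}__{i}"] = w
    np.savez(path, **arrays)
    meta = {
        "epoch": snapshot.epoch,
        "metrics": snapshot.metrics,
        "chromosome": list(snapshot.arch.chromosome.filters),
        "n_channels": snapshot.arch.n_channels,
        "n_inception": snapshot.arch.n_inception,
        "input_side": snapshot.arch.input_side,
        "dropout": snapshot.arch.dropout,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_snapshot(path: str | Path) -> Snapshot:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arch = build_architecture(
        tuple(meta["chromosome"]), meta["n_channels"], meta["n_inception"],
        meta["input_side"], meta["dropout"],
    )
    npz = np.load(path.with_suffix(".npz"))
    state: dict[str, list[np.ndarray]] = {}
    for key in npz.files:
        name, i = key.rsplit("__", 1)
        state.setdefault(name, [None, None])[int(i)] = npz[key]
    return Snapshot(epoch=meta["epoch"], state=state, metrics=meta["metrics"], arch=arch)
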