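"""Refinement experiments: inception-depth sweep and two-phase input selection.

These drivers reproduce the structure-refinement protocol on phantom data:

* ``depth_sweep`` — train the classifier with a varying number of inception
  blocks (all input channels) and tabulate mean validation accuracy against
  analytic FLOPs; deeper variants cost strictly more FLOPs and, on the
  phantom task, tend to overfit relative to 1-2 blocks.
* ``feature_phase1`` — train one single-channel classifier per canonical
  channel; channels whose mean validation accuracy strictly exceeds the
  selection threshold (default 0.55, chance level being 1/3) are selected.
  On phantoms only the first-polar-body and germinal-vesicle channels are
  informative by construction.
* ``feature_phase2`` — starting from the selected {FPB, GV} base, add each
  remaining channel individually (the base-only run is kept as the reference
  row) and rank the combinations by mean validation accuracy.

Every run reports per-repetition validation and test accuracies over an SRRS
plan; accuracy is the fraction of correctly staged oocytes on the balanced
validation/test draw.  All randomness is derived from the config seeds, so
reports are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import TensorDataset
from .classifier import build_architecture, count_flops, predict_labels, select_snapshot, train_classifier, TrainConfig
from .dataio import ChannelSelection
from .records import CANONICAL_CHANNELS, FPB, GV
from .sampling import SrrsPlan, epoch_reseed, srrs_split

__all__ = ["ExperimentConfig", "ChannelRunResult", "FeatureSelectionReport",
           "run_channel_experiment", "depth_sweep", "feature_phase1", "feature_phase2",
           "chromosome_evaluator"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale sweep budget: small phantoms, few epochs, tiny chromosomes."""

    plan: SrrsPlan = field(default_factory=lambda: SrrsPlan(
        repetitions=3,
        validation={"MI": 20, "MII": 20, "PI": 20},
        test={"MI": 20, "MII": 20, "PI": 20},
    ))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=8, batch_size=30, steps_per_epoch=4, learning_rate=2e-2))
    chromosome: tuple[int, ...] = (16, 16, 8, 16, 16, 8)
    n_inception: int = 1
    input_side: int = 64
    threshold: float = 0.55


@dataclass
class ChannelRunResult:
    channels: tuple[str, ...]
    val_accuracy: float
    test_accuracy: float
    per_repetition: pd.DataFrame   # columns: srrs_id, val_accuracy, test_accuracy
    test_correct: int
    test_total: int


@dataclass
class FeatureSelectionReport:
    phase: int
    rows: pd.DataFrame             # channel set, mean val/test accuracy
    threshold: float
    selected: tuple[str, ...]      # phase 1: channels with Acc̄ strictly above threshold


def _ids_by_class(records) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for r in records:
        out.setdefault(r.label, []).append(r.id)
    return out


def run_channel_experiment(records, channels, cfg: ExperimentConfig,
                           merge_fpb: bool = False, n_inception: int | None = None) -> ChannelRunResult:
    """Train/evaluate one channel combination over the SRRS plan."""
    channels = tuple(channels)
    n_inception = cfg.n_inception if n_inception is None else n_inception
    selection = ChannelSelection(channels, merge_fpb=merge_fpb)
    ds = TensorDataset.from_records(records, selection, side=cfg.input_side)
    splits = srrs_split(_ids_by_class(records), cfg.plan)
    arch = build_architecture(cfg.chromosome, len(selection.ordered), n_inception, cfg.input_side)
    rows = []
    correct = total = 0
    for rep_id in range(len(splits)):
        rep = splits[rep_id]
        tc = replace(cfg.train, seed=epoch_reseed(rep_id, cfg.train.seed))
        best = select_snapshot(train_classifier(ds, rep, arch, tc))
        pred = predict_labels(ds, rep["test"], best) if rep["test"] else []
        truth = [ds.labels[i] for i in rep["test"]]
        n_ok = sum(p == t for p, t in zip(pred, truth))
        correct += n_ok
        total += len(truth)
        rows.append({
            "srrs_id": rep_id,
            "val_accuracy": best.metrics["val_accuracy"],
            "test_accuracy": n_ok / len(truth) if truth else np.nan,
        })
    per_rep = pd.DataFrame(rows)
    return ChannelRunResult(
        channels=channels,
        val_accuracy=float(per_rep["val_accuracy"].mean()),
        test_accuracy=float(per_rep["test_accuracy"].mean()) if total else float("nan"),
        per_repetition=per_rep,
        test_correct=correct,
        test_total=total,
    )


def depth_sweep(records, cfg: ExperimentConfig, blocks=(4, 3, 2, 1, 0)) -> pd.DataFrame:
    """Accuracy and FLOPs per inception-block count (all canonical channels)."""
    rows = []
    for b in blocks:
        try:
            res = run_channel_experiment(records, CANONICAL_CHANNELS, cfg, n_inception=b)
        except Exception as exc:
            raise RuntimeError(f"depth sweep failed at {b} inception blocks: {exc}") from exc
        arch = build_architecture(cfg.chromosome, len(CANONICAL_CHANNELS), b, cfg.input_side)
        rows.append({"blocks": b, "val_accuracy": res.val_accuracy,
                     "test_accuracy": res.test_accuracy, "flops": count_flops(arch)})
    return pd.DataFrame(rows)


def feature_phase1(records, cfg: ExperimentConfig, channels=CANONICAL_CHANNELS) -> FeatureSelectionReport:
    """One single-channel training per canonical channel; threshold selection."""
    rows = []
    for ch in channels:
        try:
            res = run_channel_experiment(records, (ch,), cfg)
            rows.append({"channels": ch, "val_accuracy": res.val_accuracy,
                         "test_accuracy": res.test_accuracy,
                         "test_correct": res.test_correct, "test_total": res.test_total})
        except Exception as exc:  # keep sweeping; report the failure in-row
            rows.append({"channels": ch, "val_accuracy": np.nan, "test_accuracy": np.nan,
                         "test_correct": 0, "test_total": 0, "error": str(exc)})
    df = pd.DataFrame(rows)
    selected = tuple(df.loc[df["val_accuracy"] > cfg.threshold, "channels"])
    return FeatureSelectionReport(phase=1, rows=df, threshold=cfg.threshold, selected=selected)


def feature_phase2(records, cfg: ExperimentConfig, base=(FPB, GV), extras=None) -> FeatureSelectionReport:
    """Add each remaining channel to the base set; base-only is the reference."""
    base = tuple(base)
    if extras is None:
        extras = tuple(c for c in CANONICAL_CHANNELS if c not in base)
    rows = []
    for extra in (None, *extras):
        channels = base if extra is None else tuple(sorted(base + (extra,), key=CANONICAL_CHANNELS.index))
        try:
            res = run_channel_experiment(records, channels, cfg)
            rows.append({"added": extra or "(base only)", "channels": " + ".join(channels),
                         "val_accuracy": res.val_accuracy, "test_accuracy": res.test_accuracy})
        except Exception as exc:
            rows.append({"added": extra or "(base only)", "channels": " + ".join(channels),
                         "val_accuracy": np.nan, "test_accuracy": np.nan, "error": str(exc)})
    df = pd.DataFrame(rows).sort_values("val_accuracy", ascending=False, kind="stable").reset_index(drop=True)
    return FeatureSelectionReport(phase=2, rows=df, threshold=cfg.threshold, selected=base)


def chromosome_evaluator(records, cfg: ExperimentConfig, channels=(FPB, GV), merge_fpb: bool = True):
    """Acc̄ evaluator for the GA: one training per chromosome on the first split.

    The tensor store and split are precomputed once; each call trains the
    candidate architecture and returns its best validation accuracy.  A final
    confirmation run of the GA winner over the full SRRS plan remains the
    caller's job (see :func:`run_channel_experiment`).
    """
    selection = ChannelSelection(tuple(channels), merge_fpb=merge_fpb)
    ds = TensorDataset.from_records(records, selection, side=cfg.input_side)
    split = srrs_split(_ids_by_class(records), cfg.plan)[0]

    def evaluate(chromosome) -> float:
        arch = build_architecture(chromosome, len(selection.ordered), cfg.n_inception, cfg.input_side)
        best = select_snapshot(train_classifier(ds, split, arch, cfg.train))
        return best.metrics["val_accuracy"]

    return evaluate
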