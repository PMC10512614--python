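"""Quality coefficients: per-class confusion metrics, IoU, SRRS means, DR.

Evaluation follows a one-vs-rest decomposition of the three maturity classes:
each SRRS repetition produces per-class Tp/Fp/Fn/Tn tallies, from which
per-class ACC, TPR (recall), PPV (precision), FDR and f1 are derived.  The
suite is aggregated in two nested unweighted means: first across classes
within a repetition, then across SRRS repetitions:

    X̄ = (1/SRRS_N) Σ_k (1/CLASS_N) Σ_c X_c^(k)

Segmentation quality uses per-class intersection-over-union and the
*detection ratio* DR — the fraction of ground-truth regions whose predicted
mask overlaps them by at least 100 correct pixels.

Conventions (documented in the methods note): per-class ACC defaults to the
standard binary accuracy (Tp+Tn)/(Tp+Tn+Fp+Fn); the alternative
``as-printed`` convention Tp/(Tp+Tn) is kept selectable for auditing.
Degenerate denominators yield 0 and are flagged.  IoU of two empty masks is
1 (vacuous agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import LABELS

__all__ = [
    "ConfusionTally",
    "tally_from_predictions",
    "per_class_metrics",
    "iou",
    "aggregate",
    "detection_ratio",
    "MetricsReport",
]

METRIC_NAMES = ("ACC", "TPR", "PPV", "FDR", "f1")


@dataclass
class ConfusionTally:
    """One-vs-rest Tp/Fp/Fn/Tn per class for a single SRRS repetition."""

    counts: dict[str, dict[str, int]]  # class -> {"Tp","Fp","Fn","Tn"}
    srrs_id: int = 0

    def n_samples(self) -> int:
        c = next(iter(self.counts.values()))
        return c["Tp"] + c["Fp"] + c["Fn"] + c["Tn"]

    def validate(self) -> "ConfusionTally":
        n = self.n_samples()
        for cls, c in self.counts.items():
            if any(v < 0 for v in c.values()):
                raise ValueError(f"negative count in class {cls}")
            if c["Tp"] + c["Fp"] + c["Fn"] + c["Tn"] != n:
                raise ValueError("per-class counts are inconsistent in total")
        return self


def tally_from_predictions(true_labels, predicted_labels, srrs_id: int = 0) -> ConfusionTally:
    """One-vs-rest confusion counts from paired label sequences."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    for lab in set(true_labels) | set(predicted_labels):
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
    counts = {}
    for cls in LABELS:
        t = np.array([lab == cls for lab in true_labels])
        p = np.array([lab == cls for lab in predicted_labels])
        counts[cls] = {
            "Tp": int(np.sum(t & p)),
            "Fp": int(np.sum(~t & p)),
            "Fn": int(np.sum(t & ~p)),
            "Tn": int(np.sum(~t & ~p)),
        }
    return ConfusionTally(counts=counts, srrs_id=srrs_id).validate()


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def per_class_metrics(tally: ConfusionTally, acc_convention: str = "standard") -> pd.DataFrame:
    """ACC/TPR/PPV/FDR/f1 per class; rows are classes, plus a ``degenerate`` flag.

    ``acc_convention``: ``"standard"`` uses (Tp+Tn)/(Tp+Tn+Fp+Fn);
    ``"as-printed"`` uses the literal Tp/(Tp+Tn) variant.
    """
    if acc_convention not in ("standard", "as-printed"):
        raise ValueError("acc_convention must be 'standard' or 'as-printed'")
    tally.validate()
    rows = {}
    for cls, c in tally.counts.items():
        tp, fp, fn, tn = c["Tp"], c["Fp"], c["Fn"], c["Tn"]
        tpr, d1 = _safe_div(tp, tp + fn)
        ppv, d2 = _safe_div(tp, tp + fp)
        fdr, _ = _safe_div(fp, fp + tp)
        if acc_convention == "standard":
            acc, d3 = _safe_div(tp + tn, tp + tn + fp + fn)
        else:
            acc, d3 = _safe_div(tp, tp + tn)
        f1, d4 = _safe_div(2 * ppv * tpr, ppv + tpr)
        rows[cls] = {
            "ACC": acc, "TPR": tpr, "PPV": ppv, "FDR": fdr, "f1": f1,
            "degenerate": d1 or d2 or d3 or d4,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def iou(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; empty vs empty gives 1."""
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    p = predicted.astype(bool)
    t = truth.astype(bool)
    union = np.sum(p | t)
    if union == 0:
        return 1.0
    return float(np.sum(p & t) / union)


@dataclass
class MetricsReport:
    """Per-repetition and cross-repetition quality-coefficient means."""

    per_class: pd.DataFrame          # index (srrs_id, class), columns METRIC_NAMES
    per_repetition: pd.DataFrame     # index srrs_id, columns METRIC_NAMES (class means)
    means: dict[str, float]          # cross-repetition means, e.g. {"ACC": ...}
    degenerate: bool = False

    def summary(self) -> pd.Series:
        return pd.Series(self.means)


def aggregate(tallies: list[ConfusionTally], acc_convention: str = "standard") -> MetricsReport:
    """Two-level unweighted means: classes within repetition, then repetitions."""
    if not tallies:
        raise ValueError("at least one tally is required")
    per_class_frames = []
    for t in tallies:
        missing = [c for c in LABELS if c not in t.counts]
        if missing:
            raise ValueError(f"repetition {t.srrs_id} is missing class {missing[0]}")
        df = per_class_metrics(t, acc_convention)
        df.index = pd.MultiIndex.from_product([[t.srrs_id], df.index], names=["srrs_id", "class"])
        per_class_frames.append(df)
    per_class = pd.concat(per_class_frames)
    degenerate = bool(per_class["degenerate"].any())
    values = per_class[list(METRIC_NAMES)]
    per_rep = values.groupby(level="srrs_id").mean()
    means = per_rep.mean(axis=0).to_dict()
    return MetricsReport(per_class=per_class, per_repetition=per_rep, means=means, degenerate=degenerate)


def detection_ratio(outcomes) -> float:
    """Fraction of (oocyte, region) ground-truth regions that were detected."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("detection ratio of an empty outcome set is undefined")
    return float(np.mean([bool(o) for o in outcomes]))
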