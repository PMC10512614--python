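"""Stratified repeated random subsampling (SRRS) and class-balanced batches.

The clinical maturity distribution is heavily imbalanced (MII dominates), so
model evaluation uses SRRS: the dataset is partitioned ``repetitions`` times
into train/validation/test with *fixed per-class* validation and test counts
(stratification), the remainder forming the training pool.  Training batches
are class-balanced — each of the three classes contributes batch_size/3
records, drawn with replacement when a class is rarer than its quota — and
are redrawn from a fresh deterministic seed at the start of every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import LABELS

__all__ = ["SrrsPlan", "SplitAssignment", "srrs_split", "balanced_batch", "epoch_reseed"]


@dataclass(frozen=True)
class SrrsPlan:
    """Per-class validation/test allocation and the repetition count.

    The default counts follow the printed segmentation-side plan
    (5/5/5 validation, 9/58/24 test); repetitions default to 3, with 10 used
    for final confirmation runs.
    """

    repetitions: int = 3
    validation: dict[str, int] = field(default_factory=lambda: {"MI": 5, "MII": 5, "PI": 5})
    test: dict[str, int] = field(default_factory=lambda: {"MI": 9, "MII": 58, "PI": 24})
    seed: int = 0

    def validate(self) -> "SrrsPlan":
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for part in (self.validation, self.test):
            for c, n in part.items():
                if c not in LABELS or n < 0:
                    raise ValueError(f"invalid plan entry {c}={n}")
        return self


@dataclass
class SplitAssignment:
    """Per-repetition partition of record ids into train/validation/test."""

    repetitions: list[dict[str, list[str]]]  # each: {"train": [...], "val": [...], "test": [...]}

    def __getitem__(self, i: int) -> dict[str, list[str]]:
        return self.repetitions[i]

    def __len__(self) -> int:
        return len(self.repetitions)


def srrs_split(ids_by_class: dict[str, list[str]], plan: SrrsPlan) -> SplitAssignment:
    """Draw the SRRS partitions.

    ``ids_by_class`` maps each maturity class to its record ids.  For every
    repetition the per-class validation and test counts are drawn without
    replacement; the remainder is the training set.  Deterministic under the
    plan seed; repetitions use distinct sub-seeds.
    """
    plan.validate()
    for c, n_val in plan.validation.items():
        avail = len(ids_by_class.get(c, []))
        if n_val + plan.test.get(c, 0) > avail:
            raise ValueError(
                f"plan infeasible for class {c}: validation {n_val} + test {plan.test.get(c, 0)} "
                f"> {avail} available records"
            )
    reps = []
    for r in range(plan.repetitions):
        rng = np.random.default_rng(np.random.SeedSequence([plan.seed, r]))
        train, val, test = [], [], []
        for c in LABELS:
            ids = sorted(ids_by_class.get(c, []))
            perm = [ids[i] for i in rng.permutation(len(ids))]
            n_val, n_test = plan.validation.get(c, 0), plan.test.get(c, 0)
            val += perm[:n_val]
            test += perm[n_val : n_val + n_test]
            train += perm[n_val + n_test :]
        reps.append({"train": train, "val": val, "test": test})
    return SplitAssignment(repetitions=reps)


def balanced_batch(ids_by_class: dict[str, list[str]], batch_size: int = 84, seed: int = 0) -> list[str]:
    """Draw one class-balanced training batch (batch_size/n_classes per class).

    Classes rarer than their quota are sampled with replacement; the draw is
    deterministic for a given seed, so per-epoch variation comes from
    :func:`epoch_reseed`.
    """
    classes = [c for c in LABELS if c in ids_by_class]
    if not classes or any(len(ids_by_class[c]) == 0 for c in classes):
        raise ValueError("every class must have at least one training record")
    if batch_size % len(classes):
        raise ValueError(f"batch size {batch_size} not divisible by {len(classes)} classes")
    quota = batch_size // len(classes)
    rng = np.random.default_rng(seed)
    batch: list[str] = []
    for c in classes:
        ids = sorted(ids_by_class[c])
        replace = len(ids) < quota
        picks = rng.choice(len(ids), size=quota, replace=replace)
        batch += [ids[i] for i in picks]
    return batch


def epoch_reseed(epoch: int, base_seed: int) -> int:
    """Deterministic per-epoch seed so batch composition varies across epochs."""
    return int(np.random.SeedSequence([base_seed, epoch]).generate_state(1)[0] % 2**31)
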