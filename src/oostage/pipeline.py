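"""End-to-end orchestration: phantoms → splits → segmenter → classifier → reports.

``run_experiment`` executes the full study on phantom data: generate a
class-conditional phantom dataset, draw SRRS splits, train the segmenter and
the 2-channel (FPB+GV) classifier per repetition, and evaluate the
classifier twice on identical splits — once on the ground-truth ("manual")
masks and once on masks predicted by the segmenter — emitting a
coefficient × {validation, test, all} report for both mask sources, plus the
segmenter's DR/IoU.  Every artifact is reproducible from the config and its
seeds alone; re-running a config yields byte-identical reports.

``classify_image`` is the deployment path for a single image: segment,
merge the polar-body masks, assemble the 2-channel tensor, pad to the
classifier input and classify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentConfig, TensorDataset
from .classifier import (Snapshot, TrainConfig, build_architecture, classify, predict_labels,
                         select_snapshot, train_classifier)
from .dataio import ChannelSelection, RESOLUTION_LIMIT, assemble_tensor, normalize_resolution, pad_tensor
from .metrics import MetricsReport, aggregate, iou, tally_from_predictions
from .phantom import PhantomParams, generate_dataset
from .records import FPB, GV, OocyteRecord
from .sampling import SrrsPlan, epoch_reseed, srrs_split
from .segmentation import (SegConfig, SegSnapshot, predict_masks, region_detected,
                           select_segmenter, train_segmenter)

__all__ = ["PipelineConfig", "classify_image", "run_experiment"]

CLASSIFIER_SELECTION = ChannelSelection((FPB, GV), merge_fpb=True)


@dataclass(frozen=True)
class PipelineConfig:
    """Desk-scale defaults: 100 phantoms/class at 128 px, classifier at 136 px
    (128 + 8 px shift frame), segmenter at 64 px."""

    seed: int = 0
    output_dir: str = "runs/experiment"
    phantom_counts: dict[str, int] = field(default_factory=lambda: {"MI": 100, "MII": 100, "PI": 100})
    phantom: PhantomParams = field(default_factory=lambda: PhantomParams(side=128))
    srrs: SrrsPlan = field(default_factory=lambda: SrrsPlan(
        repetitions=2,
        validation={"MI": 5, "MII": 5, "PI": 5},
        test={"MI": 15, "MII": 15, "PI": 15},
    ))
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(
        n_rot=2, n_shift=1, shift_range=8, output_side=136))
    classifier: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=12, batch_size=30, steps_per_epoch=4, learning_rate=2e-2))
    chromosome: tuple[int, ...] = (16, 16, 8, 16, 16, 8)
    n_inception: int = 1
    segmentation: SegConfig = field(default_factory=lambda: SegConfig(
        input_side=64, epochs=16, brightness_jitter=0.2))
    acc_convention: str = "standard"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("seed", "output_dir", "phantom_counts", "chromosome", "n_inception", "acc_convention"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "chromosome" else raw[key]
        if "phantom" in raw:
            kwargs["phantom"] = PhantomParams(**{k: tuple(v) if isinstance(v, list) else v
                                                 for k, v in raw["phantom"].items()})
        if "srrs" in raw:
            kwargs["srrs"] = SrrsPlan(**raw["srrs"])
        if "augment" in raw:
            kwargs["augment"] = AugmentConfig(**raw["augment"])
        if "classifier" in raw:
            kwargs["classifier"] = TrainConfig(**raw["classifier"])
        if "segmentation" in raw:
            kwargs["segmentation"] = SegConfig(**raw["segmentation"])
        return cls(**kwargs)


def classify_image(image: np.ndarray, seg_snapshot: SegSnapshot, clf_snapshot: Snapshot,
                   bounding_box=None):
    """Stage one oocyte image: segmentation → 2-channel tensor → classifier.

    Returns (label, probabilities, masks); the masks are the predicted GV and
    FPB planes actually fed to the classifier (in source-crop geometry).
    """
    if clf_snapshot.arch.n_channels != 2:
        raise ValueError("classifier snapshot must accept the 2-channel FPB+GV input")
    masks = predict_masks(image, seg_snapshot, bounding_box)
    if bounding_box is not None:
        r0, c0, r1, c1 = bounding_box
        image = image[r0:r1, c0:c1]
    rec = OocyteRecord(id="query", image=image, masks={k: v for k, v in masks.items() if v.any()})
    side = clf_snapshot.arch.input_side
    rec = normalize_resolution(rec, min(RESOLUTION_LIMIT, side))
    tensor = pad_tensor(assemble_tensor(rec, CLASSIFIER_SELECTION), side)
    label, probs = classify(tensor, clf_snapshot)
    return label, probs, masks


def _manual_tensor(record: OocyteRecord, side: int):
    rec = normalize_resolution(record, min(RESOLUTION_LIMIT, side))
    return pad_tensor(assemble_tensor(rec, CLASSIFIER_SELECTION), side)


def _segmentation_scores(records, seg_snapshot: SegSnapshot) -> tuple[float, float, dict[str, np.ndarray]]:
    """DR and mean IoU of predicted masks at source geometry; masks returned."""
    from .dataio import merge_fpb_masks

    outcomes, ious, pred_cache = [], [], {}
    for rec in records:
        pred = predict_masks(rec.image, seg_snapshot)
        pred_cache[rec.id] = pred
        truth = merge_fpb_masks(rec)
        for region in (GV, FPB):
            t = truth.mask(region)
            ious.append(iou(pred[region], t))
            if t.any():
                outcomes.append(region_detected(pred[region], t))
    dr = float(np.mean(outcomes)) if outcomes else 1.0
    return dr, float(np.mean(ious)), pred_cache


def run_experiment(config: PipelineConfig, records=None) -> dict:
    """Run the configured experiment; returns reports and writes artifacts.

    ``records`` may inject a pre-generated phantom dataset (the config's
    phantom block is then ignored).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if records is None:
        records, _ = generate_dataset(config.phantom_counts, config.phantom, seed=config.seed)
    by_id = {r.id: r for r in records}
    ids_by_class: dict[str, list[str]] = {}
    for r in records:
        ids_by_class.setdefault(r.label, []).append(r.id)

    plan = replace(config.srrs, seed=epoch_reseed(1, config.seed))
    splits = srrs_split(ids_by_class, plan)
    (out_dir / "splits.json").write_text(json.dumps(splits.repetitions, indent=1))

    clf_side = config.augment.output_side
    arch = build_architecture(config.chromosome, 2, config.n_inception, clf_side)
    ds = TensorDataset.from_records(records, CLASSIFIER_SELECTION, cfg=config.augment)

    tallies = {("manual", s): [] for s in ("validation", "test", "all")}
    tallies.update({("predicted", s): [] for s in ("validation", "test", "all")})
    seg_rows = []
    for rep_id in range(len(splits)):
        rep = splits[rep_id]
        rep_seed = epoch_reseed(rep_id, config.seed)

        seg_cfg = replace(config.segmentation, seed=rep_seed)
        seg_snaps = train_segmenter([by_id[i] for i in rep["train"]], seg_cfg,
                                    val_records=[by_id[i] for i in rep["val"]])
        seg_best = select_segmenter(seg_snaps)

        clf_cfg = replace(config.classifier, seed=rep_seed)
        clf_best = select_snapshot(train_classifier(ds, rep, arch, clf_cfg))

        eval_sets = {"validation": rep["val"], "test": rep["test"],
                     "all": rep["train"] + rep["val"] + rep["test"]}
        # predicted masks for every oocyte this repetition touches
        dr_val, iou_val, _ = _segmentation_scores([by_id[i] for i in rep["val"]], seg_best)
        dr_test, iou_test, _ = _segmentation_scores([by_id[i] for i in rep["test"]], seg_best)
        seg_rows.append({"srrs_id": rep_id, "val_DR": dr_val, "val_IoU": iou_val,
                         "test_DR": dr_test, "test_IoU": iou_test,
                         "selected_epoch": seg_best.epoch})
        for set_name, ids in eval_sets.items():
            truth = [by_id[i].label for i in ids]
            manual_pred = predict_labels(ds, ids, clf_best)
            tallies[("manual", set_name)].append(tally_from_predictions(truth, manual_pred, rep_id))
            pipe_pred = [classify_image(by_id[i].image, seg_best, clf_best)[0] for i in ids]
            tallies[("predicted", set_name)].append(tally_from_predictions(truth, pipe_pred, rep_id))

    # coefficient × {validation, test, all} table for both mask sources
    columns = {}
    reports: dict[tuple[str, str], MetricsReport] = {}
    for key, tl in tallies.items():
        rep = aggregate(tl, acc_convention=config.acc_convention)
        reports[key] = rep
        columns[key] = rep.means
    table = pd.DataFrame(columns)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["masks", "set"])
    seg_table = pd.DataFrame(seg_rows)

    table.to_csv(out_dir / "classification_report.csv")
    seg_table.to_csv(out_dir / "segmentation_report.csv", index=False)
    (out_dir / "classification_report.json").write_text(
        json.dumps({f"{m}/{s}": v for (m, s), v in columns.items()}, indent=1, sort_keys=True))
    return {"classification": table, "segmentation": seg_table,
            "reports": reports, "splits": splits, "output_dir": out_dir}
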