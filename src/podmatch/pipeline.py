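"""End-to-end experiment driver: synthesize -> detect -> fuse -> count -> evaluate.

The detector stage is pluggable: ``oracle`` derives perfect detections from
the synthetic scene truth (isolating the correction stage), while ``file``
ingests external detector output in either detection dialect.  Every
stochastic stage draws its seed from the run seed, so a rerun with the same
configuration writes byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detections import PodSet, flip_boxes
from .imaging import crop_and_resize, mirror_flip, write_image
from .matching import MatchConfig, fuse_plant, model_scorer, oracle_scorer
from .metrics import CountEvalReport, acc, evaluate_counts
from .synth import SceneTruth, SynthConfig, generate_scene, truth_to_detections

log = logging.getLogger("podmatch")

COUNT_COLUMNS = ["plant_id", "one", "two", "three", "four", "total"]
_CAT_TO_CLASS = {"one": 1, "two": 2, "three": 3, "four": 4}


@dataclass
class RunConfig:
    n_scenes: int = 20
    synth: SynthConfig = field(default_factory=SynthConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    scorer: str = "oracle"          # "oracle" or "model"
    model_path: str | None = None
    out_dir: str = "runs/experiment"
    seed: int = 0
    save_images: bool = False

    def __post_init__(self) -> None:
        if self.scorer not in ("oracle", "model"):
            raise ValueError(f"unknown scorer {self.scorer!r}")
        if self.scorer == "model" and not self.model_path:
            raise ValueError("scorer 'model' needs model_path")


def counts_row(plant_id: str, counts: dict) -> dict:
    row = {"plant_id": plant_id}
    for cat, cls in _CAT_TO_CLASS.items():
        row[cat] = int(counts.get(cls, counts.get(cat, 0)))
    row["total"] = int(counts.get("total", sum(row[c] for c in _CAT_TO_CLASS)))
    return row


def podset_counts_row(plant_id: str, podset: PodSet) -> dict:
    return counts_row(plant_id, podset.class_histogram())


def _acc_or_nan(truth: float, predict: float) -> float:
    """Per-category count accuracy; a correctly predicted empty category counts
    as perfect, an invented pod in an empty category is undefined (NaN)."""
    if truth > 0:
        return acc(truth, predict)
    return 1.0 if predict == 0 else float("nan")


def compare_single_vs_fused(counts_front: pd.DataFrame, counts_fused: pd.DataFrame,
                            truth: pd.DataFrame) -> pd.DataFrame:
    """Per-plant accuracy table for single-view vs fused counting.

    One row per plant: per-category Acc for both methods, their five-category
    means, and the fused-minus-front difference.
    """
    cats = ["one", "two", "three", "four", "total"]
    merged = truth.merge(counts_front, on="plant_id", suffixes=("", "_front")) \
                  .merge(counts_fused.rename(columns={c: f"{c}_fused" for c in cats}),
                         on="plant_id")
    if len(merged) != len(truth):
        raise ValueError("plant_id mismatch across count tables")
    rows = []
    for _, rec in merged.iterrows():
        row = {"plant_id": rec["plant_id"]}
        for method in ("front", "fused"):
            accs = [_acc_or_nan(rec[cat], rec[f"{cat}_{method}"]) for cat in cats]
            for cat, a in zip(cats, accs):
                row[f"acc_{method}_{cat}"] = a
            row[f"acc_mean_{method}"] = float(np.nanmean(accs))
        row["acc_mean_diff"] = row["acc_mean_fused"] - row["acc_mean_front"]
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_acc_mean(truth: pd.DataFrame, pred: pd.DataFrame) -> float:
    """Five-category mean accuracy on counts summed over all plants."""
    from .metrics import acc_mean
    cats = ["one", "two", "three", "four", "total"]
    merged = truth.merge(pred, on="plant_id", suffixes=("_t", "_c"))
    return acc_mean([acc(float(merged[f"{c}_t"].sum()), float(merged[f"{c}_c"].sum()))
                     for c in cats])


def fuse_scene(truth: SceneTruth, front_img: np.ndarray, rear_img: np.ndarray,
               scorer_kind: str, match_cfg: MatchConfig, model=None):
    """Oracle-detect both views of one synthetic scene, align, and fuse."""
    w = truth.image_size[0]
    front = truth_to_detections(truth, "front")
    rear = flip_boxes(truth_to_detections(truth, "rear"), w)
    if scorer_kind == "oracle":
        scorer = oracle_scorer
    else:
        scorer = model_scorer(model, front_img, mirror_flip(rear_img))
    result, count = fuse_plant(front, rear, scorer, match_cfg)
    return front, rear, result, count


def run_experiment(cfg: RunConfig):
    """Run the full synthetic experiment and write all report artifacts.

    Returns (truth_table, front_table, fused_table, comparison, fused_report,
    front_report) after writing counts CSVs, comparison CSV, per-category
    count-metric CSVs, a per-plant match audit JSON, and a manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = None
    if cfg.scorer == "model":
        from .siamese import SimilarityModel
        model = SimilarityModel.load(cfg.model_path)
    truth_rows, front_rows, fused_rows = [], [], []
    audit = {}
    for k in range(cfg.n_scenes):
        scene_cfg = SynthConfig(**{**asdict(cfg.synth),
                                   "seed": int(cfg.seed * 100003 + k)})
        front_img, rear_img, truth = generate_scene(scene_cfg)
        plant_id = f"plant{k:04d}"
        front, rear, result, count = fuse_scene(
            truth, front_img, rear_img, cfg.scorer, cfg.match, model=model)
        truth_rows.append(counts_row(plant_id, truth.true_counts))
        front_rows.append(podset_counts_row(plant_id, front))
        fused_rows.append(counts_row(plant_id, count.as_dict()))
        audit[plant_id] = {
            "pairs": [[int(i), int(j), float(s)] for i, j, s in result.pairs],
            "front_only": [int(i) for i in result.front_only],
            "rear_only": [int(j) for j in result.rear_only],
        }
        if cfg.save_images:
            write_image(out / f"{plant_id}_front.png", front_img)
            write_image(out / f"{plant_id}_rear.png", rear_img)
            (out / f"{plant_id}_truth.json").write_text(truth.to_json())
        log.info("%s: %d front, %d rear, %d pairs -> total %d (truth %d)",
                 plant_id, len(front), len(rear), len(result.pairs),
                 count.total, truth.true_counts["total"])
    truth_table = pd.DataFrame(truth_rows, columns=COUNT_COLUMNS)
    front_table = pd.DataFrame(front_rows, columns=COUNT_COLUMNS)
    fused_table = pd.DataFrame(fused_rows, columns=COUNT_COLUMNS)
    comparison = compare_single_vs_fused(front_table, fused_table, truth_table)
    fused_report = evaluate_counts(truth_table, fused_table)
    front_report = evaluate_counts(truth_table, front_table)

    truth_table.to_csv(out / "counts_truth.csv", index=False)
    front_table.to_csv(out / "counts_front.csv", index=False)
    fused_table.to_csv(out / "counts_fused.csv", index=False)
    comparison.to_csv(out / "comparison.csv", index=False)
    fused_report.to_frame().to_csv(out / "count_eval_fused.csv", index=False)
    front_report.to_frame().to_csv(out / "count_eval_front.csv", index=False)
    (out / "match_audit.json").write_text(json.dumps(audit, indent=1, sort_keys=True))
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "config_sha256": hashlib.sha256(
            json.dumps(_config_dict(cfg), sort_keys=True).encode()).hexdigest(),
        "n_scenes": cfg.n_scenes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return truth_table, front_table, fused_table, comparison, fused_report, front_report


def _config_dict(cfg: RunConfig) -> dict:
    # the output path is not part of the scientific configuration
    d = asdict(cfg)
    d.pop("out_dir", None)
    return d


def collect_training_crops(n_scenes: int, seed: int, synth: SynthConfig | None = None,
                           side: int = 105, pad: int = 2):
    """Harvest per-view pod crops with class labels from synthetic scenes.

    Both views contribute crops (the rear image mirror-aligned first), exactly
    as real crops would be cut from detector output.  Returns (crops, labels).
    """
    base = synth or SynthConfig()
    crops, labels = [], []
    for k in range(n_scenes):
        scfg = SynthConfig(**{**asdict(base), "seed": int(seed * 99991 + k)})
        front_img, rear_img, truth = generate_scene(scfg)
        rear_aligned = mirror_flip(rear_img)
        w = truth.image_size[0]
        for view, img in (("front", front_img), ("rear", rear_aligned)):
            dets = truth_to_detections(truth, view)
            if view == "rear":
                dets = flip_boxes(dets, w)
            for d in dets:
                crops.append(crop_and_resize(img, d, pad=pad, side=side))
                labels.append(d.pod_class)
    return crops, labels
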