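"""Cross-view correction matching and deduplicated pod counting.

Given the frontal pod set f and the (mirror-aligned) rear pod set p of the
same plant, each frontal pod is greedily matched to the most similar
remaining rear pod; a similarity strictly above the threshold (default 0.5)
declares the two detections the same physical pod.  Matched pairs count
once, and survivors on either side count as pods seen from only one side —
this is what recovers pods occluded in a single view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .detections import PodSet, VALID_CLASSES
from .imaging import crop_and_resize


@dataclass
class MatchConfig:
    threshold: float = 0.5
    row_order: str = "confidence_desc"       # or "index"
    class_conflict: str = "higher_confidence"  # or "frontal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.row_order not in ("confidence_desc", "index"):
            raise ValueError(f"unknown row_order {self.row_order!r}")
        if self.class_conflict not in ("higher_confidence", "frontal"):
            raise ValueError(f"unknown class_conflict {self.class_conflict!r}")


@dataclass
class MatchResult:
    """Partition of both detection index sets: pairs + one-view survivors."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    front_only: list[int] = field(default_factory=list)
    rear_only: list[int] = field(default_factory=list)

    @property
    def n_pods(self) -> int:
        return len(self.pairs) + len(self.front_only) + len(self.rear_only)


@dataclass
class PlantCount:
    counts: dict[int, int]

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in sorted(VALID_CLASSES)}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict:
        d = {c: self.counts[c] for c in sorted(VALID_CLASSES)}
        d["total"] = self.total
        return d


def greedy_match(sim: np.ndarray, cfg: MatchConfig | None = None,
                 row_priority=None) -> MatchResult:
    """Sequential greedy matching of frontal rows to rear columns.

    Rows are visited in ``cfg.row_order``: by descending ``row_priority``
    (detection confidence; ties by index) or by index.  Each visited row takes
    the argmax over the rear columns not yet claimed; if that similarity is
    strictly greater than the threshold the pair is emitted and both are
    removed, otherwise the row is recorded as front-only.  Columns left at
    the end are rear-only.  Ties in the argmax go to the lowest column index.
    """
    cfg = cfg or MatchConfig()
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2:
        sim = sim.reshape((sim.shape[0] if sim.size else 0, -1))
    if sim.size and not np.isfinite(sim).all():
        raise ValueError("similarity matrix contains non-finite entries")
    nf, nr = sim.shape
    if cfg.row_order == "confidence_desc" and row_priority is not None:
        prio = np.asarray(row_priority, dtype=float)
        order = sorted(range(nf), key=lambda i: (-prio[i], i))
    else:
        order = list(range(nf))
    result = MatchResult()
    free = np.ones(nr, dtype=bool)
    for i in order:
        if free.any():
            scores = np.where(free, sim[i], -np.inf)
            j = int(np.argmax(scores))  # argmax takes the first (lowest) index on ties
            if scores[j] > cfg.threshold:
                result.pairs.append((i, j, float(sim[i, j])))
                free[j] = False
                continue
        result.front_only.append(i)
    result.rear_only = [j for j in range(nr) if free[j]]
    return result


def count_from_match(result: MatchResult, front: PodSet, rear: PodSet,
                     cfg: MatchConfig | None = None) -> PlantCount:
    """Per-class deduplicated count: pairs once, survivors once each.

    When a matched pair disagrees on class, ``cfg.class_conflict`` picks the
    winner: the higher-confidence detection (frontal on a tie) or always the
    frontal one.
    """
    cfg = cfg or MatchConfig()
    counts = {c: 0 for c in sorted(VALID_CLASSES)}
    for i, j, _ in result.pairs:
        df, dr = front[i], rear[j]
        if df.pod_class == dr.pod_class or cfg.class_conflict == "frontal":
            cls = df.pod_class
        else:
            cls = df.pod_class if df.confidence >= dr.confidence else dr.pod_class
        counts[cls] += 1
    for i in result.front_only:
        counts[front[i].pod_class] += 1
    for j in result.rear_only:
        counts[rear[j].pod_class] += 1
    return PlantCount(counts)


def similarity_matrix(front: PodSet, rear: PodSet,
                      scorer: Callable) -> np.ndarray:
    """|f| x |p| matrix of pairwise similarity scores in [0, 1]."""
    sim = np.zeros((len(front), len(rear)))
    for i, df in enumerate(front):
        for j, dr in enumerate(rear):
            sim[i, j] = scorer(df, dr)
    return sim


def oracle_scorer(front_det, rear_det) -> float:
    """Identity oracle: 1 iff the two detections come from the same pod.

    Only meaningful on synthetic detections carrying ``source_id``; isolates
    the matching and counting stages from the learned similarity model.
    """
    if front_det.source_id is None or rear_det.source_id is None:
        raise ValueError("oracle similarity needs source_id on both detections")
    return 1.0 if front_det.source_id == rear_det.source_id else 0.0


def model_scorer(model, front_image: np.ndarray, rear_image_aligned: np.ndarray,
                 pad: int = 2):
    """Build a scorer closure around a similarity model and the two images.

    ``rear_image_aligned`` must already be mirror-flipped into the front
    frame, with the rear boxes flipped to match.  Crops are cached per
    detection object.
    """
    cache: dict[int, np.ndarray] = {}

    def crop_of(det, image):
        key = id(det)
        if key not in cache:
            cache[key] = crop_and_resize(image, det, pad=pad, side=model.config.input_side)
        return cache[key]

    def scorer(df, dr) -> float:
        return float(model.similarity(crop_of(df, front_image),
                                      crop_of(dr, rear_image_aligned)))
    return scorer


def fuse_plant(front: PodSet, rear: PodSet, scorer: Callable,
               cfg: MatchConfig | None = None) -> tuple[MatchResult, PlantCount]:
    """Score all cross-view pairs, match greedily, and count.

    ``scorer(front_det, rear_det) -> [0,1]`` may be :func:`oracle_scorer`, a
    closure from :func:`model_scorer`, or any custom callable.  The rear set
    must be mirror-aligned with the front frame.
    """
    cfg = cfg or MatchConfig()
    sim = similarity_matrix(front, rear, scorer)
    priorities = [d.confidence for d in front]
    result = greedy_match(sim, cfg, row_priority=priorities)
    return result, count_from_match(result, front, rear, cfg)
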