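"""Synthetic paired front/rear pod scenes with known identity and occlusion.

A scene is a set of multi-lobed pods (1-4 tangent lobes = seeds per pod)
scattered on a white background, photographed "from both sides": the rear
image is rendered in mirrored camera geometry, exactly as a physically
rotated plant would appear, so the standard mirror-flip realigns it with the
front view.  Each pod may be hidden in at most one view (occlusion), and the
ground truth records identity, class, per-view visibility and boxes — which
makes every downstream stage (cropping, similarity, matching, counting,
metric computation) testable without any photograph.

Per-pod appearance is jittered independently per view (lobe size, hue,
angle), so two views of the same pod are similar but not pixel-identical;
this is what makes the similarity-learning task non-trivial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .detections import BoundingBox, Detection, PodSet, VALID_CLASSES
from .imaging import mirror_flip, salt_pepper

# class mix follows the field-observed pod-type imbalance: two- and
# three-seed pods dominate, one- and four-seed pods are rare
DEFAULT_CLASS_PROBS = (0.1035, 0.3297, 0.4674, 0.0994)

# base pod hue (BGR-ish olive green) on white background
_POD_COLOR = np.array([107.0, 142.0, 35.0])


@dataclass(frozen=True)
class PodSpec:
    """Ground-truth description of one pod."""

    pod_id: int
    pod_class: int          # seeds per pod, 1..4 (= number of lobes)
    center: tuple[float, float]  # (x, y) pixels in the front/aligned frame
    angle: float            # axis angle in degrees
    lobe_radius: float      # px
    visible_front: bool = True
    visible_rear: bool = True

    def __post_init__(self) -> None:
        if self.pod_class not in VALID_CLASSES:
            raise ValueError(f"pod class must be in {sorted(VALID_CLASSES)}, got {self.pod_class}")
        if self.lobe_radius <= 0:
            raise ValueError("lobe_radius must be positive")
        if not (self.visible_front or self.visible_rear):
            raise ValueError("a counted pod must be visible in at least one view")


@dataclass
class SceneTruth:
    """Everything the generator knows about one synthetic plant."""

    pods: list[PodSpec]
    image_size: tuple[int, int]            # (width, height)
    seed: int
    front_boxes: dict[int, BoundingBox] = field(default_factory=dict)
    rear_boxes: dict[int, BoundingBox] = field(default_factory=dict)  # as-captured frame

    @property
    def true_counts(self) -> dict:
        counts = {c: 0 for c in sorted(VALID_CLASSES)}
        for p in self.pods:
            counts[p.pod_class] += 1
        counts["total"] = len(self.pods)
        return counts

    def to_json(self) -> str:
        def _box(b: BoundingBox) -> list[float]:
            return [b.x_min, b.y_min, b.x_max, b.y_max]
        payload = {
            "image_size": list(self.image_size),
            "seed": self.seed,
            "true_counts": {str(k): v for k, v in self.true_counts.items()},
            "pods": [{
                "pod_id": p.pod_id, "pod_class": p.pod_class,
                "center": list(p.center), "angle": p.angle,
                "lobe_radius": p.lobe_radius,
                "visible_front": p.visible_front, "visible_rear": p.visible_rear,
                "front_box": _box(self.front_boxes[p.pod_id]) if p.pod_id in self.front_boxes else None,
                "rear_box": _box(self.rear_boxes[p.pod_id]) if p.pod_id in self.rear_boxes else None,
            } for p in self.pods],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        data = json.loads(text)
        pods, fb, rb = [], {}, {}
        for rec in data["pods"]:
            pods.append(PodSpec(
                pod_id=rec["pod_id"], pod_class=rec["pod_class"],
                center=tuple(rec["center"]), angle=rec["angle"],
                lobe_radius=rec["lobe_radius"],
                visible_front=rec["visible_front"], visible_rear=rec["visible_rear"]))
            if rec.get("front_box"):
                fb[rec["pod_id"]] = BoundingBox(*rec["front_box"])
            if rec.get("rear_box"):
                rb[rec["pod_id"]] = BoundingBox(*rec["rear_box"])
        return cls(pods=pods, image_size=tuple(data["image_size"]), seed=data["seed"],
                   front_boxes=fb, rear_boxes=rb)


@dataclass
class SynthConfig:
    """Study conditions for scene generation."""

    n_pods_range: tuple[int, int] = (10, 40)
    class_probabilities: tuple[float, float, float, float] = DEFAULT_CLASS_PROBS
    occlusion_rate: float = 0.2     # P(pod hidden in exactly one view)
    noise_level: float = 0.0        # salt-and-pepper pixel fraction
    image_size: tuple[int, int] = (640, 480)
    lobe_radius_range: tuple[float, float] = (8.0, 13.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image_size must have positive area")
        if not 0.0 <= self.occlusion_rate < 1.0:
            raise ValueError("occlusion_rate must be in [0, 1)")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise_level must be in [0, 1]")
        p = np.asarray(self.class_probabilities, dtype=float)
        if p.size != 4 or (p < 0).any() or p.sum() <= 0:
            raise ValueError("class_probabilities needs 4 nonnegative weights")
        self.class_probabilities = tuple(p / p.sum())


def render_pod(spec: PodSpec, canvas: np.ndarray,
               color: np.ndarray | None = None) -> tuple[np.ndarray, BoundingBox]:
    """Paint one pod as ``pod_class`` tangent elliptical lobes along its axis.

    Deterministic given the spec; returns the canvas (modified in place) and
    the tight half-open bounding box of the painted pixels.
    """
    if spec.pod_class not in VALID_CLASSES:
        raise ValueError(f"invalid pod class {spec.pod_class}")
    h, w = canvas.shape[:2]
    col = _POD_COLOR if color is None else np.asarray(color, dtype=float)
    theta = math.radians(spec.angle)
    dx, dy = math.cos(theta), math.sin(theta)
    a = spec.lobe_radius          # semi-axis along the pod axis
    b = 0.8 * spec.lobe_radius    # semi-axis across it
    n = spec.pod_class
    # lobe centers spaced 2a apart (tangent), centred on spec.center
    offsets = (np.arange(n) - (n - 1) / 2.0) * 2.0 * a
    rows_all, cols_all = [], []
    for off in offsets:
        cx = spec.center[0] + off * dx
        cy = spec.center[1] + off * dy
        rr, cc = draw_ellipse(cy, cx, b, a, shape=(h, w), rotation=-theta)
        if rr.size:
            shade = col * (0.88 + 0.24 * ((off - offsets[0]) / (abs(offsets[-1] - offsets[0]) + 1e-9)
                                          if n > 1 else 0.5))
            canvas[rr, cc] = np.clip(shade, 0, 255).astype(canvas.dtype)
            rows_all.append(rr)
            cols_all.append(cc)
    if not rows_all:
        raise ValueError(f"pod {spec.pod_id} fell entirely outside the canvas")
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    box = BoundingBox(float(cols.min()), float(rows.min()),
                      float(cols.max()) + 1.0, float(rows.max()) + 1.0)
    return canvas, box


def _jitter(spec: PodSpec, rng: np.random.Generator) -> tuple[PodSpec, np.ndarray]:
    """Per-view appearance perturbation: same identity, slightly different look."""
    radius = spec.lobe_radius * float(rng.uniform(0.93, 1.07))
    angle = spec.angle + float(rng.uniform(-6.0, 6.0))
    color = _POD_COLOR + rng.uniform(-18.0, 18.0, size=3)
    jittered = PodSpec(pod_id=spec.pod_id, pod_class=spec.pod_class, center=spec.center,
                       angle=angle, lobe_radius=radius,
                       visible_front=spec.visible_front, visible_rear=spec.visible_rear)
    return jittered, color


def generate_scene(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Render one paired scene.

    Draw order from ``cfg.seed`` (fixed so results are replayable): pod count,
    classes, centers, angles, lobe radii, then the occlusion mask (uniform draw
    per pod, then a fair coin for which view hides it), then per-pod front and
    rear jitters, then image noise.  The returned rear image is mirrored
    (as captured); ``SceneTruth.rear_boxes`` live in that mirrored frame.
    """
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.image_size
    lo, hi = cfg.n_pods_range
    n = int(rng.integers(lo, hi + 1))
    classes = rng.choice(np.arange(1, 5), size=n, p=np.asarray(cfg.class_probabilities))
    # margin keeps every pod fully on canvas: longest pod = 4 lobes * 2a
    max_half = 4.0 * cfg.lobe_radius_range[1] + 2.0
    cx = rng.uniform(max_half, w - max_half, size=n)
    cy = rng.uniform(max_half, h - max_half, size=n)
    angles = rng.uniform(0.0, 180.0, size=n)
    radii = rng.uniform(*cfg.lobe_radius_range, size=n)
    hidden = rng.random(n) < cfg.occlusion_rate
    hide_front = rng.integers(0, 2, size=n).astype(bool)  # True: hidden from front

    pods = [PodSpec(pod_id=i, pod_class=int(classes[i]), center=(float(cx[i]), float(cy[i])),
                    angle=float(angles[i]), lobe_radius=float(radii[i]),
                    visible_front=not (hidden[i] and hide_front[i]),
                    visible_rear=not (hidden[i] and not hide_front[i]))
            for i in range(n)]

    front = np.full((h, w, 3), 255, dtype=np.uint8)
    rear_aligned = np.full((h, w, 3), 255, dtype=np.uint8)
    truth = SceneTruth(pods=pods, image_size=(w, h), seed=cfg.seed)
    for p in pods:
        front_spec, front_color = _jitter(p, rng)
        rear_spec, rear_color = _jitter(p, rng)
        if p.visible_front:
            _, box = render_pod(front_spec, front, color=front_color)
            truth.front_boxes[p.pod_id] = box
        if p.visible_rear:
            _, box = render_pod(rear_spec, rear_aligned, color=rear_color)
            # box recorded in the as-captured (mirrored) rear frame
            truth.rear_boxes[p.pod_id] = BoundingBox(
                w - box.x_max, box.y_min, w - box.x_min, box.y_max)
    rear = mirror_flip(rear_aligned)
    if cfg.noise_level > 0:
        front = salt_pepper(front, cfg.noise_level, rng)
        rear = salt_pepper(rear, cfg.noise_level, rng)
    return front, rear, truth


def truth_to_detections(truth: SceneTruth, view: str) -> PodSet:
    """Oracle detector: one unit-confidence detection per pod visible in ``view``.

    Rear boxes are in the as-captured mirrored frame, exactly like a real
    detector run on the rear photograph; downstream realignment is the
    caller's job.  Ordered by pod_id; ``source_id`` carries identity.
    """
    if view not in ("front", "rear"):
        raise ValueError(f"view must be 'front' or 'rear', got {view!r}")
    boxes = truth.front_boxes if view == "front" else truth.rear_boxes
    dets = [Detection(box=boxes[p.pod_id], pod_class=p.pod_class, confidence=1.0,
                      view=view, source_id=p.pod_id)
            for p in sorted(truth.pods, key=lambda q: q.pod_id)
            if p.pod_id in boxes]
    return PodSet(plant_id=f"scene{truth.seed}", view=view, detections=dets)


def sample_pairs(labels, n_pairs: int, positive_fraction: float = 0.5,
                 seed: int = 0) -> list[tuple[int, int, int]]:
    """Sample (i, j, label) index pairs for verification training.

    label 1 = same class, 0 = different class.  The number of positive pairs
    is ``round(positive_fraction * n_pairs)`` exactly.  Positive pairs draw
    their class uniformly among classes holding at least two crops (class
    balance); negatives draw two distinct classes uniformly.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    labels = list(labels)
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for i, c in enumerate(labels):
        by_class.setdefault(int(c), []).append(i)
    classes = sorted(by_class)
    n_pos = int(round(positive_fraction * n_pairs))
    n_neg = n_pairs - n_pos
    pos_classes = [c for c in classes if len(by_class[c]) >= 2]
    if n_pos > 0 and not pos_classes:
        raise ValueError("positive pairs requested but no class has >= 2 crops")
    if n_neg > 0 and len(classes) < 2:
        raise ValueError("negative pairs requested but only one class present")
    pairs: list[tuple[int, int, int]] = []
    for _ in range(n_pos):
        c = pos_classes[int(rng.integers(len(pos_classes)))]
        i, j = rng.choice(len(by_class[c]), size=2, replace=False)
        pairs.append((by_class[c][int(i)], by_class[c][int(j)], 1))
    for _ in range(n_neg):
        ca, cb = rng.choice(len(classes), size=2, replace=False)
        ia = int(rng.integers(len(by_class[classes[int(ca)]])))
        ib = int(rng.integers(len(by_class[classes[int(cb)]])))
        pairs.append((by_class[classes[int(ca)]][ia], by_class[classes[int(cb)]][ib], 0))
    order = rng.permutation(len(pairs))
    return [pairs[int(k)] for k in order]
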