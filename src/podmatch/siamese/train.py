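"""Pair training and prototype-based evaluation for the similarity model."""

from __future__ import annotations

import warnings

import numpy as np

from .model import SimilarityModel, _sigmoid
from .nn import make_optimizer

_EPS = 1e-7


def crops_to_batch(crops) -> np.ndarray:
    """List of HxWx3 float crops in [0,1] -> (N, 3, H, W) float32 batch."""
    arr = np.stack([np.asarray(c, dtype=np.float32) for c in crops])
    if arr.ndim == 3:
        arr = np.repeat(arr[:, None], 3, axis=1)
    else:
        arr = arr.transpose(0, 3, 1, 2)
    return np.ascontiguousarray(arr)


def pair_accuracy(scores: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of pairs where (score > 0.5) agrees with the same-class label."""
    return float(np.mean((scores > 0.5) == (labels > 0.5)))


def _bce(scores: np.ndarray, labels: np.ndarray) -> float:
    s = np.clip(scores, _EPS, 1.0 - _EPS)
    return float(-np.mean(labels * np.log(s) + (1 - labels) * np.log(1 - s)))


def train_pairs(model: SimilarityModel, crops, pairs, cfg=None,
                val_pairs=None) -> tuple[SimilarityModel, list[dict]]:
    """Train the twin network on labeled same/different-class crop pairs.

    ``pairs`` is a list of ``(i, j, label)`` index triples into ``crops``
    (label 1 = same class).  Minimizes binary cross-entropy of the similarity
    score against the label, with seeded shuffling per epoch; returns the
    model and a per-epoch history of train loss/accuracy (and validation
    accuracy when ``val_pairs`` is given).  Zero epochs returns the model
    untouched with an empty history.
    """
    cfg = cfg or model.config
    labels = np.asarray([p[2] for p in pairs], dtype=np.float64)
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    if labels.min() == labels.max():
        warnings.warn("degenerate pair labels: all pairs share one label",
                      stacklevel=2)
    history: list[dict] = []
    if cfg.epochs == 0:
        return model, history
    batch_all = crops_to_batch(crops)
    rng = np.random.default_rng(cfg.seed)
    model.head.dropout.reseed(cfg.seed + 2)
    opt = make_optimizer(cfg.optimizer, model.params(), cfg.learning_rate)
    ia = np.asarray([p[0] for p in pairs])
    ib = np.asarray([p[1] for p in pairs])
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        losses, accs = [], []
        for start in range(0, len(pairs), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xa = batch_all[ia[sel]]
            xb = batch_all[ib[sel]]
            y = labels[sel]
            scores = model.score_pairs(xa, xb, train=True)
            losses.append(_bce(scores, y))
            accs.append(pair_accuracy(scores, y))
            # d(BCE)/d(logit) = (sigmoid(logit) - y) / batch
            model.zero_grad()
            model.backward_pairs(((scores - y) / len(sel)).astype(np.float32))
            opt.step()
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                  "train_acc": float(np.mean(accs))}
        if val_pairs is not None:
            record["val_acc"] = evaluate_pairs(model, crops, val_pairs,
                                               batch=batch_all)[1]
        history.append(record)
    return model, history


def evaluate_pairs(model: SimilarityModel, crops, pairs,
                   batch: np.ndarray | None = None,
                   batch_size: int = 64) -> tuple[np.ndarray, float]:
    """Eval-mode scores and pair accuracy on a labeled pair list."""
    if batch is None:
        batch = crops_to_batch(crops)
    ia = np.asarray([p[0] for p in pairs])
    ib = np.asarray([p[1] for p in pairs])
    labels = np.asarray([p[2] for p in pairs], dtype=np.float64)
    scores = np.empty(len(pairs))
    for start in range(0, len(pairs), batch_size):
        sl = slice(start, start + batch_size)
        scores[sl] = model.score_pairs(batch[ia[sl]], batch[ib[sl]], train=False)
    return scores, pair_accuracy(scores, labels)


def evaluate_confusion(model: SimilarityModel, query_crops, query_labels,
                       reference_crops, reference_labels,
                       classes=(1, 2, 3, 4)) -> np.ndarray:
    """Prototype classification confusion matrix (rows truth, columns prediction).

    Each query is assigned the class whose reference crops have the highest
    mean similarity to it; ties break to the lowest class index.  Row sums
    equal the per-class query counts.
    """
    ref_labels = np.asarray(reference_labels)
    if len(reference_crops) == 0:
        raise ValueError("empty reference set")
    for cls in classes:
        if not np.any(ref_labels == cls):
            raise ValueError(f"no reference crops for class {cls}")
    q_emb = model.embed(crops_to_batch(query_crops))
    r_emb = model.embed(crops_to_batch(reference_crops))
    nq, nr = len(q_emb), len(r_emb)
    feat = np.abs(q_emb[:, None, :] - r_emb[None, :, :]).reshape(nq * nr, -1)
    logits = model.head.forward(feat.astype(np.float32), train=False)[:, 0]
    scores = _sigmoid(logits).reshape(nq, nr)
    class_scores = np.stack([scores[:, ref_labels == cls].mean(axis=1)
                             for cls in classes], axis=1)
    pred_idx = np.argmax(class_scores, axis=1)  # first max -> lowest class on ties
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    cls_index = {c: k for k, c in enumerate(classes)}
    for ql, pi in zip(np.asarray(query_labels), pred_idx):
        cm[cls_index[int(ql)], pi] += 1
    return cm
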