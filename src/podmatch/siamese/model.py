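"""The twin-branch similarity model: shared backbone, verification head.

Both crops pass through the *same* embedding network (true weight sharing —
the twin branches are one object), and the verification head is a logistic
classifier on the element-wise absolute difference of the two embeddings:

    score(a, b) = sigmoid( head(|e(a) - e(b)|) )

The absolute difference makes the score exactly symmetric in its arguments,
which the downstream matching stage assumes; a zeroed head gives
sigmoid(0) = 0.5 for every pair.  Training minimizes binary cross-entropy of
the score against the same-class pair label.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .backbone import EmbeddingNet, build_backbone
from .nn import Dropout, Layer, Linear, ReLU

DEFAULT_HIDDEN = 32


@dataclass
class SiameseConfig:
    input_side: int = 105
    backbone: str = "se_resnet_tiny"
    embedding_dim: int = 64
    dropout_rate: float = 0.2
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    epochs: int = 8
    se_reduction: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class VerificationHead(Layer):
    """Two fully connected layers with dropout in between; outputs a logit."""

    def __init__(self, in_dim: int, hidden: int = DEFAULT_HIDDEN,
                 dropout_rate: float = 0.2, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(in_dim, hidden, rng=rng, dtype=dtype)
        self.relu = ReLU()
        self.dropout = Dropout(dropout_rate)
        self.fc2 = Linear(hidden, 1, rng=rng, dtype=dtype)

    def forward(self, x, train: bool = False):
        x = self.fc1.forward(x, train=train)
        x = self.relu.forward(x, train=train)
        x = self.dropout.forward(x, train=train)
        return self.fc2.forward(x, train=train)

    def backward(self, dout):
        dout = self.fc2.backward(dout)
        dout = self.dropout.backward(dout)
        dout = self.relu.backward(dout)
        return self.fc1.backward(dout)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class SimilarityModel:
    """Shared-weight twin embedding network + verification head."""

    def __init__(self, config: SiameseConfig | None = None, dtype=np.float32):
        self.config = config or SiameseConfig()
        self.backbone: EmbeddingNet = build_backbone(
            self.config.backbone, embedding_dim=self.config.embedding_dim,
            se_reduction=self.config.se_reduction, seed=self.config.seed, dtype=dtype)
        head_rng = np.random.default_rng(self.config.seed + 1)
        self.head = VerificationHead(self.config.embedding_dim,
                                     dropout_rate=self.config.dropout_rate,
                                     rng=head_rng, dtype=dtype)
        self.head.dropout.reseed(self.config.seed + 2)
        self._cache = None

    # ---- parameters ----------------------------------------------------
    def named_params(self):
        return ([(f"backbone.{n}", p) for n, p in self.backbone.named_params()]
                + [(f"head.{n}", p) for n, p in self.head.named_params()])

    def params(self):
        return [p for _, p in self.named_params()]

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0

    # ---- inference -----------------------------------------------------
    @staticmethod
    def _as_batch(crop: np.ndarray) -> np.ndarray:
        """HWC or HW float crop -> (1, 3, H, W)."""
        c = np.asarray(crop, dtype=np.float32)
        if c.ndim == 2:
            c = np.stack([c] * 3, axis=-1)
        if c.ndim == 3 and c.shape[-1] in (1, 3):
            if c.shape[-1] == 1:
                c = np.repeat(c, 3, axis=-1)
            c = c.transpose(2, 0, 1)
        return c[None]

    def embed(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 3, side, side) -> (N, embedding_dim)."""
        side = self.config.input_side
        if batch.shape[-2:] != (side, side):
            raise ValueError(f"crops must be {side}x{side}, got {batch.shape[-2:]}")
        return self.backbone.forward(batch, train=train)

    def score_pairs(self, xa: np.ndarray, xb: np.ndarray,
                    train: bool = False) -> np.ndarray:
        """Similarity scores for aligned crop batches (N, 3, side, side).

        The twin forwards run as one stacked batch so batch-norm statistics
        and the backward pass treat both branches identically.
        """
        n = xa.shape[0]
        emb = self.embed(np.concatenate([xa, xb], axis=0), train=train)
        e1, e2 = emb[:n], emb[n:]
        diff = e1 - e2
        feat = np.abs(diff)
        logit = self.head.forward(feat, train=train)[:, 0]
        self._cache = (np.sign(diff), n)
        return _sigmoid(logit)

    def backward_pairs(self, dlogit: np.ndarray) -> None:
        """Backprop from d(loss)/d(logit) through head and shared backbone."""
        sign, n = self._cache
        dfeat = self.head.backward(dlogit[:, None])
        ddiff = dfeat * sign
        self.backbone.backward(np.concatenate([ddiff, -ddiff], axis=0))

    def similarity(self, crop_a: np.ndarray, crop_b: np.ndarray) -> float:
        """Score one crop pair in [0, 1]; symmetric and deterministic (eval mode)."""
        return float(self.score_pairs(self._as_batch(crop_a), self._as_batch(crop_b))[0])

    # ---- checkpointing -------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write config (JSON sidecar inside the npz) and all weights/stats."""
        from .nn import BatchNorm2d
        arrays = {f"param/{n}": p.data for n, p in self.named_params()}
        for i, bn in enumerate(m for m in self.backbone.modules()
                               if isinstance(m, BatchNorm2d)):
            arrays[f"bn/{i}/mean"] = bn.running_mean
            arrays[f"bn/{i}/var"] = bn.running_var
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SimilarityModel":
        from .nn import BatchNorm2d
        with np.load(path) as data:
            cfg = SiameseConfig(**json.loads(bytes(data["config_json"]).decode()))
            model = cls(cfg)
            params = dict(model.named_params())
            for key in data.files:
                if key.startswith("param/"):
                    params[key[len("param/"):]].data = data[key].copy()
            bns = [m for m in model.backbone.modules() if isinstance(m, BatchNorm2d)]
            for i, bn in enumerate(bns):
                bn.running_mean = data[f"bn/{i}/mean"].copy()
                bn.running_var = data[f"bn/{i}/var"].copy()
        return model
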