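"""Image alignment, crop extraction, and training-set augmentation.

The rear photograph of a plant is taken after a 180-degree physical rotation,
so its pixel grid is a mirror of the front view; :func:`mirror_flip` realigns
it.  Crops feed the similarity network and are normalized to a fixed square
side (105 px by default) with intensities in [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .detections import Detection

DEFAULT_CROP_SIDE = 105
DEFAULT_CROP_PAD = 2


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path))


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.ascontiguousarray(image))


def mirror_flip(image: np.ndarray) -> np.ndarray:
    """Horizontal reflection (column c -> width-1-c). Involution."""
    if image.size == 0:
        raise ValueError("empty image")
    return image[:, ::-1].copy()


def rotate180(image: np.ndarray) -> np.ndarray:
    """180-degree rotation = horizontal then vertical mirror."""
    return image[::-1, ::-1].copy()


def crop_and_resize(image: np.ndarray, det: Detection, pad: int = DEFAULT_CROP_PAD,
                    side: int = DEFAULT_CROP_SIDE) -> np.ndarray:
    """Cut the detection's box (expanded by ``pad``, clipped to the image)
    and resize to ``side``x``side`` float32 in [0, 1].
    """
    h, w = image.shape[:2]
    b = det.box
    x0 = max(0, int(np.floor(b.x_min)) - pad)
    y0 = max(0, int(np.floor(b.y_min)) - pad)
    x1 = min(w, int(np.ceil(b.x_max)) + pad)
    y1 = min(h, int(np.ceil(b.y_max)) + pad)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"box {b} does not intersect image of shape {(h, w)}")
    patch = np.asarray(image[y0:y1, x0:x1], dtype=np.float64)
    if np.issubdtype(image.dtype, np.integer):
        patch = patch / float(np.iinfo(image.dtype).max)
    out_shape = (side, side) if patch.ndim == 2 else (side, side, patch.shape[2])
    out = resize(patch, out_shape, order=1, mode="edge", anti_aliasing=False,
                 preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def salt_pepper(image: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each pixel to the minimum or maximum value with probability p/2 each.

    For multi-channel images the whole pixel is set, which matches the visual
    appearance of salt-and-pepper corruption on photographs.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"noise probability must be in [0, 1], got {p}")
    out = image.copy()
    if p == 0.0:
        return out
    lo, hi = ((0, np.iinfo(image.dtype).max) if np.issubdtype(image.dtype, np.integer)
              else (0.0, 1.0))
    u = rng.random(image.shape[:2])
    out[u < p / 2] = lo
    out[(u >= p / 2) & (u < p)] = hi
    return out


def augment(crop: np.ndarray, ops: tuple = (), seed: int | None = None) -> np.ndarray:
    """Apply augmentation ops in the order listed.

    ``ops`` entries are ``"mirror"``, ``"rotate180"``, or ``("salt_pepper", p)``.
    The noise draw is seeded, so a fixed (ops, seed) pair reproduces the
    augmented crop byte-for-byte.
    """
    rng = np.random.default_rng(seed)
    out = crop
    for op in ops:
        if op == "mirror":
            out = mirror_flip(out)
        elif op == "rotate180":
            out = rotate180(out)
        elif isinstance(op, tuple) and op[0] == "salt_pepper":
            out = salt_pepper(out, float(op[1]), rng)
        else:
            raise ValueError(f"unknown augmentation op {op!r}")
    return out


def expand_dataset(crops: list[np.ndarray], noise_p: float = 0.02,
                   seed: int = 0) -> list[np.ndarray]:
    """Fourfold expansion: original + mirrored + salt-and-pepper + rotated 180."""
    out: list[np.ndarray] = []
    for i, c in enumerate(crops):
        out.append(c)
        out.append(augment(c, ops=("mirror",)))
        out.append(augment(c, ops=(("salt_pepper", noise_p),), seed=seed + i))
        out.append(augment(c, ops=("rotate180",)))
    return out
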