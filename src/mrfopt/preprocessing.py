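"""Image preprocessing: resizing, per-image scaling, balancing, splitting.

Images are standardized to 128x128 RGB by bicubic interpolation.  Four
per-image dimensional scalers are available (statistics are computed on the
single image, never across the dataset):

* ``Normalize``: X / max(X)
* ``Standard``:  (X - mean) / std
* ``MinMax``:    (X - min) / (max - min)
* ``MaxAbs``:    X / |max(X)|

Class balancing up-samples every minority class to the majority count by
re-drawing existing members with replacement and perturbing them with the
default augmentation policy (rotation 30 deg, 20% shifts/shear/zoom,
brightness in [0.8, 1.2], both flips).  Splitting is a stratified two-stage
85/15 split: test is carved off the full set first, then validation is
carved off the remaining training pool at the same ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
from PIL import Image
from skimage.transform import AffineTransform, warp
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "TARGET_SIZE",
    "AugmentationPolicy",
    "SplitResult",
    "resize_image",
    "load_image",
    "apply_scaler",
    "balance_classes",
    "balance_dataset",
    "split_dataset",
    "build_augmenter",
]

TARGET_SIZE = 128


@dataclass(frozen=True)
class AugmentationPolicy:
    """Randomized geometric/photometric perturbation settings.

    Defaults are the stock balancing policy: rotation up to 30 degrees,
    20% shifts, shear and zoom, brightness multipliers in [0.8, 1.2],
    and both flips enabled.
    """

    rotation: float = 30.0
    width_shift: float = 0.20
    height_shift: float = 0.20
    shear: float = 0.20
    zoom: float = 0.20
    brightness: tuple = (0.8, 1.2)
    horizontal_flip: bool = True
    vertical_flip: bool = True

    @classmethod
    def from_config(cls, config) -> "AugmentationPolicy":
        """Build from a :class:`~mrfopt.encoding.DecodedConfig` with augment on."""
        if not config.augment:
            raise ValueError("config has augmentation disabled")
        return cls(
            rotation=float(config.rotation),
            width_shift=config.width_shift,
            height_shift=config.height_shift,
            shear=config.shear,
            zoom=config.zoom,
            brightness=tuple(config.brightness),
            horizontal_flip=config.horizontal_flip,
            vertical_flip=config.vertical_flip,
        )


@dataclass(frozen=True)
class SplitResult:
    train_ids: np.ndarray
    validation_ids: np.ndarray
    test_ids: np.ndarray
    ratio: float

    def __post_init__(self):
        object.__setattr__(self, "train_ids", np.asarray(self.train_ids))
        object.__setattr__(self, "validation_ids", np.asarray(self.validation_ids))
        object.__setattr__(self, "test_ids", np.asarray(self.test_ids))


# -- resize ----------------------------------------------------------------


def resize_image(img: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Bicubic resize to ``size x size x 3``; grayscale is replicated to RGB."""
    arr = np.asarray(img)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise ValueError(f"expected HxW or HxWx{{1,3}} image, got shape {arr.shape}")
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[0] == size and arr.shape[1] == size:
        return arr.astype(np.float64)
    pil = Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8), mode="RGB")
    out = pil.resize((size, size), resample=Image.BICUBIC)
    return np.asarray(out, dtype=np.float64)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG file and standardize it to 128x128 RGB."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return resize_image(arr)


# -- scalers ---------------------------------------------------------------

SCALERS = ("Normalize", "Standard", "MinMax", "MaxAbs")


class DegenerateImageError(ValueError):
    """Raised when a scaler's denominator vanishes (constant/zero image)."""


def apply_scaler(
    img: np.ndarray, method: str, on_degenerate: str = "raise"
) -> np.ndarray:
    """Apply one of the four per-image dimensional scalers.

    ``on_degenerate`` controls the constant-image corner case: ``"raise"``
    signals :class:`DegenerateImageError`, ``"zeros"`` substitutes an
    all-zero image.
    """
    x = np.asarray(img, dtype=np.float64)
    if method not in SCALERS:
        raise ValueError(f"unknown scaler {method!r}; expected one of {SCALERS}")

    def degenerate():
        if on_degenerate == "zeros":
            return np.zeros_like(x)
        raise DegenerateImageError(f"{method} scaler undefined for this image")

    if method == "Normalize":
        m = x.max()
        if m == 0:
            return degenerate()
        return x / m
    if method == "Standard":
        sd = x.std()
        if sd == 0:
            return degenerate()
        return (x - x.mean()) / sd
    if method == "MinMax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return degenerate()
        return (x - lo) / (hi - lo)
    # MaxAbs
    m = abs(x.max())
    if m == 0:
        return degenerate()
    return x / m


# -- balancing -------------------------------------------------------------


def balance_classes(counts: Dict[str, int]) -> Dict[str, int]:
    """Per-class counts after up-sampling every class to the maximum count."""
    if not counts:
        raise ValueError("need at least one class")
    if any(c < 1 for c in counts.values()):
        raise ValueError("all class counts must be >= 1")
    target = max(counts.values())
    return {k: target for k in counts}


def balance_dataset(
    images: np.ndarray,
    labels: np.ndarray,
    policy: Optional[AugmentationPolicy] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Up-sample minority classes with augmented copies of existing members.

    Original images are always retained; new images are drawn with
    replacement from the class and perturbed by the policy (default: the
    stock balancing policy).  Returns ``(images, labels)`` with every class
    at the majority count.
    """
    if policy is None:
        policy = AugmentationPolicy()
    if rng is None:
        rng = np.random.default_rng(0)
    labels = np.asarray(labels)
    images = np.asarray(images, dtype=np.float64)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    aug = build_augmenter(policy)
    extra_imgs, extra_labels = [], []
    for cls, cnt in zip(classes, counts):
        deficit = int(target - cnt)
        if deficit == 0:
            continue
        pool = np.flatnonzero(labels == cls)
        picks = rng.choice(pool, size=deficit, replace=True)
        for j in picks:
            extra_imgs.append(aug(images[j], rng))
            extra_labels.append(cls)
    if not extra_imgs:
        return images, labels
    out_imgs = np.concatenate([images, np.stack(extra_imgs)], axis=0)
    out_labels = np.concatenate([labels, np.asarray(extra_labels)], axis=0)
    return out_imgs, out_labels


# -- splitting -------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    n: int,
    labels: Sequence,
    ratio: float = 0.85,
    seed: int = 0,
) -> SplitResult:
    """Two-stage stratified split at ``ratio`` (train+val) to ``1-ratio`` (test).

    The test set of size round-half-up((1-ratio)*n) is carved off first;
    validation is then carved off the remaining pool at the same fraction.
    Falls back to an unstratified split (with a warning) when a class is too
    small to stratify.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if n < 3:
        raise ValueError("need at least 3 items to split")
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    ids = np.arange(n)
    n_test = _round_half_up((1 - ratio) * n)
    n_val = _round_half_up((1 - ratio) * (n - n_test))

    def two_way(pool_ids, pool_labels, n_out, stage):
        try:
            keep, out = train_test_split(
                pool_ids,
                test_size=n_out,
                random_state=seed + stage,
                shuffle=True,
                stratify=pool_labels,
            )
        except ValueError:
            logger.warning("%s split cannot stratify; falling back to unstratified", stage)
            keep, out = train_test_split(
                pool_ids, test_size=n_out, random_state=seed + stage, shuffle=True
            )
        return keep, out

    pool, test = two_way(ids, labels, n_test, 0)
    train, val = two_way(pool, labels[pool], n_val, 1)
    return SplitResult(
        train_ids=np.sort(train),
        validation_ids=np.sort(val),
        test_ids=np.sort(test),
        ratio=ratio,
    )


# -- augmentation ----------------------------------------------------------


def build_augmenter(policy):
    """Compile a policy into a callable ``transform(image, rng) -> image``.

    The transform applies, in order: rotation (uniform in +/- range about
    the image center), width/height shifts, shear, zoom, a brightness
    multiplier drawn uniformly from the interval, and the enabled flips.
    Output shape equals input shape; intensities are clipped to [0, 255].
    """
    if hasattr(policy, "augment"):  # a DecodedConfig
        policy = AugmentationPolicy.from_config(policy)

    def transform(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = np.asarray(img, dtype=np.float64)
        h, w = x.shape[:2]
        angle = math.radians(rng.uniform(-policy.rotation, policy.rotation))
        shear = rng.uniform(-policy.shear, policy.shear)
        # zoom factor in [1-z, 1+z]
        zoom = 1.0 + rng.uniform(-policy.zoom, policy.zoom)
        tx = rng.uniform(-policy.width_shift, policy.width_shift) * w
        ty = rng.uniform(-policy.height_shift, policy.height_shift) * h
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=angle, shear=shear, scale=(zoom, zoom))
            + AffineTransform(translation=center)
            + AffineTransform(translation=(tx, ty))
        )
        identity = (
            angle == 0 and shear == 0 and zoom == 1.0 and tx == 0 and ty == 0
        )
        if not identity:
            x = warp(x, tf.inverse, mode="reflect", order=1, preserve_range=True)
        lo, hi = policy.brightness
        b = rng.uniform(lo, hi)
        x = x * b
        if policy.horizontal_flip and rng.uniform() < 0.5:
            x = x[:, ::-1]
        if policy.vertical_flip and rng.uniform() < 0.5:
            x = x[::-1, :]
        return np.clip(x, 0, 255)

    return transform
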