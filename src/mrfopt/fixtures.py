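"""Synthetic image data and reference confusion-count fixtures.

``generate_image_dataset`` renders a desk-scale multi-class image dataset
with class-dependent texture: each class combines a distinct oriented
stripe pattern with a class-specific bright quadrant, plus Gaussian pixel
noise.  The patterns are deliberately low-frequency and high-contrast so a
single-statistic threshold classifier — and hence a tiny backbone trained
for one epoch — separates the classes; this keeps end-to-end optimization
tests meaningful at desk scale.  It makes no attempt to mimic the
appearance statistics of histopathology or ultrasound imagery.

``paper_confusion_fixtures`` and ``imbalance_fixture`` return the published
per-model confusion counts and per-class image counts of the two breast
imaging benchmarks (binary histopathology, three-class ultrasound) used to
verify the metric suite and the class-balancing arithmetic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from PIL import Image

from mrfopt.metrics import ConfusionCounts

__all__ = [
    "SyntheticDatasetSpec",
    "generate_image_dataset",
    "materialize_dataset",
    "quadrant_threshold_accuracy",
    "paper_confusion_fixtures",
    "imbalance_fixture",
    "fixture_checksum",
]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of the synthetic labeled image set."""

    n_classes: int = 2
    n_per_class: int = 50
    image_size: int = 128
    noise_sd: float = 10.0
    imbalance: Optional[tuple] = None  # per-class count multipliers
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.imbalance is not None and len(self.imbalance) != self.n_classes:
            raise ValueError("imbalance must list one multiplier per class")

    def class_counts(self) -> list:
        if self.imbalance is None:
            return [self.n_per_class] * self.n_classes
        return [max(1, int(round(self.n_per_class * m))) for m in self.imbalance]


def _class_pattern(cls: int, n_classes: int, size: int) -> np.ndarray:
    """Deterministic base pattern: oriented stripes + a bright quadrant."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    angle = np.pi * cls / n_classes
    freq = 3.0 + 2.0 * cls
    stripes = np.sin(2 * np.pi * freq * (np.cos(angle) * xx + np.sin(angle) * yy))
    base = 90.0 + 50.0 * stripes
    half = size // 2
    # class-dependent intensity in the top-left quadrant: strongly separable
    base[:half, :half] += 120.0 * cls / max(1, n_classes - 1) - 60.0
    img = np.stack([base] * 3, axis=-1)
    return np.clip(img, 0, 255)


def generate_image_dataset(spec: SyntheticDatasetSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Render the dataset; returns ``(images NxHxWx3 in [0,255], labels)``."""
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for cls, count in enumerate(spec.class_counts()):
        pattern = _class_pattern(cls, spec.n_classes, spec.image_size)
        for _ in range(count):
            noise = rng.normal(0.0, spec.noise_sd, size=pattern.shape)
            images.append(np.clip(pattern + noise, 0, 255))
            labels.append(cls)
    return np.stack(images), np.asarray(labels, dtype=int)


def materialize_dataset(spec: SyntheticDatasetSpec, root) -> Path:
    """Write the dataset as class-per-subdirectory PNG folders."""
    root = Path(root)
    images, labels = generate_image_dataset(spec)
    for cls in range(spec.n_classes):
        d = root / f"class_{cls}"
        d.mkdir(parents=True, exist_ok=True)
        for j, idx in enumerate(np.flatnonzero(labels == cls)):
            Image.fromarray(images[idx].astype(np.uint8)).save(d / f"img_{j:04d}.png")
    return root


def quadrant_threshold_accuracy(
    images: np.ndarray, labels: np.ndarray, seed: int = 0
) -> float:
    """Oracle classifier: threshold on top-left-quadrant mean intensity.

    Fits the threshold on a random half of a binary dataset and reports
    accuracy on the held-out half.  Used to certify the synthetic data is
    learnable (so accuracy-based fitness tests are meaningful).
    """
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("oracle is defined for binary labels {0, 1}")
    half = images.shape[1] // 2
    stat = images[:, :half, :half].mean(axis=(1, 2, 3))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    cut = len(labels) // 2
    fit, test = order[:cut], order[cut:]
    mu0, mu1 = stat[fit][labels[fit] == 0].mean(), stat[fit][labels[fit] == 1].mean()
    thresh = (mu0 + mu1) / 2.0
    pred = (stat[test] > thresh).astype(int) if mu1 > mu0 else (stat[test] <= thresh).astype(int)
    return float((pred == labels[test]).mean())


# -- published reference fixtures -----------------------------------------

_BINARY_COUNTS = {
    "InceptionV3": (10288, 10288, 320, 320),
    "Xception": (10363, 10363, 241, 241),
    "EfficientNetB7": (7916, 7916, 2668, 2668),
    "NASNetLarge": (9817, 9817, 791, 791),
    "VGG19": (10308, 10308, 300, 300),
    "SeNet154": (10171, 10171, 413, 413),
    "DenseNet201": (10350, 10350, 242, 242),
    "ResNet152V2": (10225, 10225, 383, 383),
}

_THREECLASS_COUNTS = {
    "InceptionV3": (1191, 2521, 55, 97),
    "Xception": (1267, 2584, 32, 41),
    "EfficientNetB7": (875, 2475, 117, 421),
    "NASNetLarge": (1184, 2575, 41, 124),
    "VGG19": (1053, 2471, 121, 243),
    "SeNet154": (1257, 2572, 36, 47),
    "DenseNet201": (1204, 2491, 61, 72),
    "ResNet152V2": (1294, 2603, 13, 14),
}


def paper_confusion_fixtures() -> Dict[str, Dict[str, ConfusionCounts]]:
    """Published per-model confusion counts for the two benchmarks."""

    def build(raw):
        return {
            name: ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
            for name, (tp, tn, fp, fn) in raw.items()
        }

    return {"binary": build(_BINARY_COUNTS), "threeclass": build(_THREECLASS_COUNTS)}


def imbalance_fixture() -> Dict[str, Dict[str, int]]:
    """Published per-class image counts before balancing."""
    return {
        "binary": {"Benign": 2479, "Malignant": 5304},
        "ultrasound": {"Benign": 437, "Malignant": 210, "Normal": 133},
    }


def fixture_checksum() -> str:
    """Stable digest of the reference fixtures, guarding against edits."""
    blob = repr(sorted(_BINARY_COUNTS.items())) + repr(sorted(_THREECLASS_COUNTS.items()))
    blob += repr(sorted(imbalance_fixture()["binary"].items()))
    blob += repr(sorted(imbalance_fixture()["ultrasound"].items()))
    return hashlib.sha256(blob.encode()).hexdigest()
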