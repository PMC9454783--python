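"""Fitness functions driving the optimizer.

Two implementations of the ``evaluate(solution) -> score in [0, 1]``
contract:

* :class:`TransferFitness` — the real objective.  A decoded configuration
  selects loss, optimizer, batch size, dropout, input scaler, the fraction
  of backbone layers left trainable, and (optionally) an augmentation
  policy; the model (backbone + dropout + softmax head) is trained for a
  few epochs and scored by classification accuracy on the held-out
  validation split (score on the whole dataset is available behind
  ``eval_split="whole"`` but leaks training data into model selection and
  is off by default).

* :class:`AnalyticFitness` — ``1 / (1 + ||x - c||^2)``, a cheap unimodal
  surrogate with its maximum (exactly 1) at a known point ``c``; used for
  desk-scale optimizer verification.

Backbones come from a provider registry.  The shipped ``tiny-cnn`` provider
builds a small pooled-feature network with seeded random weights — a
synthetic stand-in for a pretrained feature extractor, sized so one-epoch
training is fast.  Any callable ``provider(seed) -> Backbone`` can be
registered under a new name, including the full-size architecture names
(InceptionV3, Xception, EfficientNetB7, NASNetLarge, VGG19, SeNet154,
DenseNet201, ResNet152V2) when a deep-learning backend is available.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from mrfopt import _nn
from mrfopt.encoding import DecodedConfig, HyperparameterSpace, decode_solution
from mrfopt.preprocessing import apply_scaler, build_augmenter

logger = logging.getLogger(__name__)

__all__ = [
    "Backbone",
    "register_backbone",
    "get_backbone",
    "available_backbones",
    "freeze_layers",
    "AnalyticFitness",
    "TransferFitness",
    "SplitData",
]


@dataclass
class Backbone:
    """An ordered stack of feature-extraction layers."""

    name: str
    layers: List[_nn.Layer]
    output_dim: int

    def __post_init__(self):
        if not self.layers:
            raise ValueError("backbone must expose at least one layer")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x


_REGISTRY: Dict[str, Callable[[int], Backbone]] = {}


def register_backbone(name: str, provider: Callable[[int], Backbone]) -> None:
    _REGISTRY[name] = provider


def available_backbones() -> List[str]:
    return sorted(_REGISTRY)


def get_backbone(name: str, seed: int = 0) -> Backbone:
    if name not in _REGISTRY:
        raise KeyError(
            f"no provider registered for backbone {name!r}; "
            f"available: {available_backbones()}"
        )
    return _REGISTRY[name](seed)


def _tiny_cnn(seed: int) -> Backbone:
    """Small pooled-feature extractor with seeded synthetic weights."""
    rng = np.random.default_rng(seed)
    pool = _nn.PoolFlatten(8)
    layers = [
        pool,
        _nn.Dense(pool.output_dim, 32, rng),
        _nn.ReLU(),
        _nn.Dense(32, 16, rng),
        _nn.ReLU(),
    ]
    return Backbone(name="tiny-cnn", layers=layers, output_dim=16)


register_backbone("tiny-cnn", _tiny_cnn)


def freeze_layers(
    layer_list: Sequence, learn_ratio: float, trailing_trainable: bool = True
):
    """Partition an ordered layer list into (frozen, trainable).

    ``learn_ratio`` is the percentage of layers left trainable; the
    trailing ``ceil(learn_ratio/100 * L)`` layers are trainable and the
    leading ones frozen.  ``trailing_trainable=False`` flips the direction
    (leading layers trainable), for users who read the ratio as the
    fraction frozen instead.
    """
    layers = list(layer_list)
    if not layers:
        raise ValueError("empty layer list: invalid backbone")
    if not 0 <= learn_ratio <= 100:
        raise ValueError("learn_ratio must be within [0, 100]")
    n_trainable = math.ceil(learn_ratio / 100.0 * len(layers))
    if trailing_trainable:
        frozen, trainable = layers[: len(layers) - n_trainable], layers[len(layers) - n_trainable :]
    else:
        trainable, frozen = layers[:n_trainable], layers[n_trainable:]
    return frozen, trainable


@dataclass
class AnalyticFitness:
    """Unimodal surrogate objective ``1 / (1 + ||x - c||^2)``."""

    target: np.ndarray

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=float)

    def __call__(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return 1.0 / (1.0 + float(((x - self.target) ** 2).sum()))


@dataclass
class SplitData:
    """Raw-intensity image splits handed to the transfer fitness."""

    train_x: np.ndarray
    train_y: np.ndarray
    val_x: np.ndarray
    val_y: np.ndarray
    test_x: np.ndarray
    test_y: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(
            max(self.train_y.max(), self.val_y.max(), self.test_y.max())
        ) + 1


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


class TransferFitness:
    """Trainable-classifier objective over decoded configurations.

    Evaluations are memoized on the decoded configuration, so the repeated
    re-scoring passes of the population sweep do not retrain identical
    configurations.  Every evaluation is seeded and appended to an optional
    JSON-lines log.
    """

    def __init__(
        self,
        data: SplitData,
        space: HyperparameterSpace,
        backbone: str = "tiny-cnn",
        epochs: int = 5,
        seed: int = 0,
        eval_split: str = "validation",
        log_path=None,
    ):
        if eval_split not in ("validation", "test", "whole"):
            raise ValueError("eval_split must be validation, test or whole")
        self.data = data
        self.space = space
        self.backbone_name = backbone
        self.epochs = int(epochs)
        self.seed = int(seed)
        self.eval_split = eval_split
        self.log_path = log_path
        self._cache: Dict[tuple, float] = {}
        get_backbone(backbone, seed)  # fail fast on unknown backbone

    # -- vector-level entry point used by the optimizer -------------------

    def __call__(self, x: np.ndarray) -> float:
        config = decode_solution(x, self.space)
        return self.evaluate(config)

    def evaluate(self, config: DecodedConfig) -> float:
        key = config.key()
        if key in self._cache:
            return self._cache[key]
        start = time.perf_counter()
        score = self._train_and_score(config)
        self._cache[key] = score
        if self.log_path is not None:
            rec = {
                "config": config.to_dict(),
                "score": score,
                "duration_s": round(time.perf_counter() - start, 4),
                "seed": self.seed,
            }
            with open(self.log_path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
        return score

    # -- training ----------------------------------------------------------

    def _scale_batch(self, images: np.ndarray, method: str) -> np.ndarray:
        return np.stack(
            [apply_scaler(img, method, on_degenerate="zeros") for img in images]
        )

    def fit_predictor(self, config: DecodedConfig):
        """Train a model under ``config``; returns ``predict(images) -> labels``.

        Returns ``None`` when training diverges (non-finite loss).
        Training is fully seeded, so repeated calls with the same
        configuration rebuild the same model.
        """
        if config.loss not in _nn.LOSS_NAMES:
            raise ValueError(f"unknown loss {config.loss!r}")
        if config.optimizer not in _nn.OPTIMIZER_NAMES:
            raise ValueError(f"unknown optimizer {config.optimizer!r}")
        data = self.data
        rng = np.random.default_rng([self.seed, 1])
        k = data.n_classes

        backbone = get_backbone(self.backbone_name, self.seed)
        _, trainable = freeze_layers(backbone.layers, config.tl_learn_ratio)
        trainable_set = {id(l) for l in trainable}
        head_dropout = _nn.Dropout(config.dropout, rng)
        head = _nn.Dense(backbone.output_dim, k, np.random.default_rng([self.seed, 2]))
        optimizer = _nn.make_optimizer(config.optimizer)
        augmenter = build_augmenter(config) if config.augment else None

        def trainable_layers():
            for layer in backbone.layers:
                if layer.params and id(layer) in trainable_set:
                    yield layer
            yield head

        n = len(data.train_y)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, config.batch_size):
                idx = order[s : s + config.batch_size]
                batch = data.train_x[idx]
                if augmenter is not None:
                    batch = np.stack([augmenter(img, rng) for img in batch])
                batch = self._scale_batch(batch, config.scaler)
                y = _one_hot(data.train_y[idx], k)

                feats = batch
                for layer in backbone.layers:
                    feats = layer.forward(feats, training=True)
                feats = head_dropout.forward(feats, training=True)
                logits = head.forward(feats, training=True)
                p = _nn.softmax(logits)
                loss, dz = _nn.loss_value_and_dz(config.loss, y, p)
                if not math.isfinite(loss):
                    logger.warning(
                        "non-finite training loss under %s/%s",
                        config.loss,
                        config.optimizer,
                    )
                    return None
                grad = head.backward(dz)
                grad = head_dropout.backward(grad)
                for layer in reversed(backbone.layers):
                    if grad is None:
                        break
                    grad = layer.backward(grad)
                optimizer.begin_step()
                for li, layer in enumerate(trainable_layers()):
                    for pname, param in layer.params.items():
                        optimizer.update((li, pname), param, layer.grads[pname])

        def predict(images: np.ndarray) -> np.ndarray:
            scaled = self._scale_batch(images, config.scaler)
            feats = backbone.forward(scaled, training=False)
            feats = head_dropout.forward(feats, training=False)
            return _nn.softmax(head.forward(feats, training=False)).argmax(axis=1)

        return predict

    def _train_and_score(self, config: DecodedConfig) -> float:
        predict = self.fit_predictor(config)
        if predict is None:
            return 0.0
        data = self.data
        if self.eval_split == "validation":
            x_eval, y_eval = data.val_x, data.val_y
        elif self.eval_split == "test":
            x_eval, y_eval = data.test_x, data.test_y
        else:  # whole dataset: validation-for-generalization variant
            x_eval = np.concatenate([data.train_x, data.val_x, data.test_x])
            y_eval = np.concatenate([data.train_y, data.val_y, data.test_y])
        acc = float((predict(x_eval) == y_eval).mean())
        return min(max(acc, 0.0), 1.0)
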