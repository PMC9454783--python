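"""Hyperparameter search space and solution decoding.

A candidate solution is a vector in ``[0, 1]^15``.  Each element is mapped
onto one concrete training hyperparameter by the linear rule

    value = lower + v * (upper - lower)

followed by a kind-specific discretisation: snapping to a step grid for
stepped-integer elements, an equal-width partition for categorical elements,
a 0.5 threshold for booleans, and an interval construction for the
brightness range.  Elements 8-15 describe the data-augmentation policy and
are only active when element 7 (the augmentation switch) decodes to true;
the optimizer nevertheless always operates in the fixed 15-dimensional cube
so the population never changes shape mid-run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "HyperparameterSpec",
    "HyperparameterSpace",
    "DecodedConfig",
    "default_space",
    "map_continuous",
    "map_stepped",
    "map_categorical",
    "map_boolean",
    "map_interval",
    "decode_solution",
    "active_dimension",
    "clip_solution",
]

KINDS = {"continuous", "stepped-integer", "categorical", "boolean", "interval"}

#: number of encoded elements when the augmentation policy is active / inactive
FULL_DIMENSION = 15
BASE_DIMENSION = 7

LOSS_LABELS = [
    "Categorical Crossentropy",
    "Categorical Hinge",
    "KLDivergence",
    "Poisson",
    "Squared Hinge",
    "Hinge",
]

OPTIMIZER_LABELS = [
    "Adam",
    "NAdam",
    "AdaGrad",
    "AdaDelta",
    "AdaMax",
    "RMSProp",
    "SGD",
    "Ftrl",
    "SGD Nesterov",
    "RMSProp Centered",
    "Adam AMSGrad",
]

SCALER_LABELS = ["Normalize", "Standard", "MinMax", "MaxAbs"]


@dataclass(frozen=True)
class HyperparameterSpec:
    """Specification of a single encoded element.

    Parameters
    ----------
    index : 1-based position of the element in the solution vector.
    name : human-readable hyperparameter name.
    kind : one of ``continuous``, ``stepped-integer``, ``categorical``,
        ``boolean``, ``interval``.
    lower, upper : numeric bounds (continuous / stepped / interval kinds).
    step : grid step (stepped-integer kind only).
    categories : ordered label list (categorical kind only).
    conditional : true for the augmentation-policy elements (8-15), which
        are decoded only when the augmentation switch is on.
    """

    index: int
    name: str
    kind: str
    lower: Optional[float] = None
    upper: Optional[float] = None
    step: Optional[float] = None
    categories: Optional[tuple] = None
    conditional: bool = False

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for element {self.index}")
        if self.kind in ("continuous", "stepped-integer", "interval"):
            if self.lower is None or self.upper is None:
                raise ValueError(f"element {self.index}: bounds required")
            if self.lower > self.upper:
                raise ValueError(f"element {self.index}: lower > upper")
        if self.kind == "stepped-integer":
            if self.step is None or self.step <= 0:
                raise ValueError(f"element {self.index}: step must be positive")
            span = self.upper - self.lower
            if abs(span / self.step - round(span / self.step)) > 1e-9:
                raise ValueError(
                    f"element {self.index}: range is not a multiple of step"
                )
        if self.kind == "categorical" and not self.categories:
            raise ValueError(f"element {self.index}: categories required")
        if self.categories is not None:
            object.__setattr__(self, "categories", tuple(self.categories))


@dataclass(frozen=True)
class HyperparameterSpace:
    """Ordered collection of the 15 element specifications."""

    specs: tuple

    def __post_init__(self):
        specs = tuple(self.specs)
        object.__setattr__(self, "specs", specs)
        if [s.index for s in specs] != list(range(1, len(specs) + 1)):
            raise ValueError("spec indices must be 1..n contiguous and ordered")
        if len(specs) != FULL_DIMENSION:
            raise ValueError(f"expected {FULL_DIMENSION} specs, got {len(specs)}")
        for s in specs:
            if s.conditional != (s.index >= 8):
                raise ValueError(
                    f"element {s.index}: conditional flag must mark elements 8-15"
                )

    def __len__(self):
        return len(self.specs)

    def __getitem__(self, index_1based: int) -> HyperparameterSpec:
        return self.specs[index_1based - 1]

    # -- serialization ----------------------------------------------------

    def to_yaml(self) -> str:
        entries = []
        for s in self.specs:
            d = {k: v for k, v in asdict(s).items() if v is not None and v is not False}
            if s.categories is not None:
                d["categories"] = list(s.categories)
            entries.append(d)
        return yaml.safe_dump({"space": entries}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "HyperparameterSpace":
        data = yaml.safe_load(text)
        specs = []
        for d in data["space"]:
            specs.append(
                HyperparameterSpec(
                    index=int(d["index"]),
                    name=d["name"],
                    kind=d["kind"],
                    lower=d.get("lower"),
                    upper=d.get("upper"),
                    step=d.get("step"),
                    categories=tuple(d["categories"]) if "categories" in d else None,
                    conditional=bool(d.get("conditional", False)),
                )
            )
        return cls(specs=tuple(specs))


def default_space(
    *,
    allow_zero_learn_ratio: bool = False,
    brightness_half_width: float = 0.05,
) -> HyperparameterSpace:
    """The stock 15-element search space.

    ``allow_zero_learn_ratio`` widens the layer-freezing element to start at
    0 (fully frozen backbone), which the stock space does not permit.
    ``brightness_half_width`` is carried on the space object via the
    returned object's companion attribute (see :func:`decode_solution`).
    """
    lr_lower = 0.0 if allow_zero_learn_ratio else 1.0
    specs = (
        HyperparameterSpec(1, "loss", "categorical", categories=tuple(LOSS_LABELS)),
        HyperparameterSpec(2, "batch_size", "stepped-integer", 4, 48, 4),
        HyperparameterSpec(3, "dropout", "continuous", 0.0, 0.6),
        HyperparameterSpec(4, "tl_learn_ratio", "stepped-integer", lr_lower, 100, 1),
        HyperparameterSpec(
            5, "optimizer", "categorical", categories=tuple(OPTIMIZER_LABELS)
        ),
        HyperparameterSpec(6, "scaler", "categorical", categories=tuple(SCALER_LABELS)),
        HyperparameterSpec(7, "augment", "boolean"),
        HyperparameterSpec(8, "rotation", "stepped-integer", 0, 45, 1, conditional=True),
        HyperparameterSpec(9, "width_shift", "continuous", 0.0, 0.25, conditional=True),
        HyperparameterSpec(10, "height_shift", "continuous", 0.0, 0.25, conditional=True),
        HyperparameterSpec(11, "shear", "continuous", 0.0, 0.25, conditional=True),
        HyperparameterSpec(12, "zoom", "continuous", 0.0, 0.25, conditional=True),
        HyperparameterSpec(13, "horizontal_flip", "boolean", conditional=True),
        HyperparameterSpec(14, "vertical_flip", "boolean", conditional=True),
        HyperparameterSpec(15, "brightness", "interval", 0.5, 2.0, conditional=True),
    )
    space = HyperparameterSpace(specs=specs)
    object.__setattr__(space, "brightness_half_width", brightness_half_width)
    return space


@dataclass(frozen=True)
class DecodedConfig:
    """Concrete training configuration obtained by decoding one solution."""

    loss: str
    batch_size: int
    dropout: float
    tl_learn_ratio: int
    optimizer: str
    scaler: str
    augment: bool
    rotation: Optional[int] = None
    width_shift: Optional[float] = None
    height_shift: Optional[float] = None
    shear: Optional[float] = None
    zoom: Optional[float] = None
    horizontal_flip: Optional[bool] = None
    vertical_flip: Optional[bool] = None
    brightness: Optional[tuple] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["brightness"] is not None:
            d["brightness"] = list(d["brightness"])
        return d

    def key(self) -> tuple:
        """Hashable identity used for fitness memoization."""
        return tuple(sorted(asdict(self).items(), key=lambda kv: kv[0]))


# -- element mappers ------------------------------------------------------


def _check_unit(v: float) -> None:
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"solution element {v!r} outside [0, 1]")


def map_continuous(v: float, lower: float, upper: float) -> float:
    """Linear map of a unit-interval value onto ``[lower, upper]``."""
    _check_unit(v)
    if lower > upper:
        raise ValueError(f"inverted bounds ({lower}, {upper})")
    return lower + v * (upper - lower)


def map_stepped(v: float, lower: float, upper: float, step: float) -> float:
    """Linear map then snap to the nearest grid point; ties round up."""
    raw = map_continuous(v, lower, upper)
    k = math.floor((raw - lower) / step + 0.5)
    k = min(max(k, 0), int(round((upper - lower) / step)))
    out = lower + k * step
    return out


def map_categorical(v: float, categories: Sequence[str]) -> str:
    """Equal-width partition of [0,1] into ``len(categories)`` cells."""
    _check_unit(v)
    if not categories:
        raise ValueError("empty category list")
    k = len(categories)
    return categories[min(int(v * k), k - 1)]


def map_boolean(v: float) -> bool:
    """False below 0.5, true at and above it."""
    _check_unit(v)
    return v >= 0.5


def map_interval(
    v: float, lower: float, upper: float, half_width: float
) -> tuple:
    """Decode a center by the linear rule, then emit a symmetric interval.

    The interval ``[c*(1-w), c*(1+w)]`` is intersected with the element
    bounds so the emitted range never escapes them.
    """
    c = map_continuous(v, lower, upper)
    lo = max(lower, c * (1.0 - half_width))
    hi = min(upper, c * (1.0 + half_width))
    return (lo, hi)


def clip_solution(x: np.ndarray) -> np.ndarray:
    """Clip a solution vector element-wise into the unit cube."""
    return np.clip(np.asarray(x, dtype=float), 0.0, 1.0)


def decode_solution(x: Sequence[float], space: HyperparameterSpace) -> DecodedConfig:
    """Decode a 15-element unit vector into a :class:`DecodedConfig`.

    Elements 8-15 are decoded only when element 7 maps to true; otherwise
    the augmentation fields are left unset.  Decoding is deterministic and
    total on the unit cube.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(space),):
        raise ValueError(f"expected a {len(space)}-element vector, got {x.shape}")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("solution vector has elements outside [0, 1]")

    w = getattr(space, "brightness_half_width", 0.05)

    def dec(i: int):
        s = space[i]
        v = float(x[i - 1])
        if s.kind == "continuous":
            return map_continuous(v, s.lower, s.upper)
        if s.kind == "stepped-integer":
            val = map_stepped(v, s.lower, s.upper, s.step)
            return int(round(val)) if float(s.step).is_integer() else val
        if s.kind == "categorical":
            return map_categorical(v, s.categories)
        if s.kind == "boolean":
            return map_boolean(v)
        if s.kind == "interval":
            return map_interval(v, s.lower, s.upper, w)
        raise ValueError(f"unhandled kind {s.kind}")  # pragma: no cover

    augment = dec(7)
    kwargs = dict(
        loss=dec(1),
        batch_size=dec(2),
        dropout=dec(3),
        tl_learn_ratio=dec(4),
        optimizer=dec(5),
        scaler=dec(6),
        augment=augment,
    )
    if augment:
        kwargs.update(
            rotation=dec(8),
            width_shift=dec(9),
            height_shift=dec(10),
            shear=dec(11),
            zoom=dec(12),
            horizontal_flip=dec(13),
            vertical_flip=dec(14),
            brightness=dec(15),
        )
    return DecodedConfig(**kwargs)


def active_dimension(config: DecodedConfig) -> int:
    """Effective dimensionality: 15 with augmentation, 7 without."""
    return FULL_DIMENSION if config.augment else BASE_DIMENSION
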