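"""Relationship functions linking the two information components.

Under the association hypothesis the information component of Y is a
deterministic function of the information component of X, I_Y = f(I_X).
A :class:`RelationshipFunction` carries the forward map, its derivative
(used for change-of-variables in the likelihood integrals), an inverse
where one exists, and the domain/range intervals that restrict the
integration limits for non-linear maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Interval",
    "RelationshipFunction",
    "fit_linear_relationship",
    "builtin_function",
    "BUILTIN_FUNCTIONS",
    "identity_function",
]

#: Relative slope magnitude below which a fitted line is treated as flat
#: (no usable inverse).
FLAT_SLOPE_TOL = 1e-12


@dataclass(frozen=True)
class Interval:
    """A closed real interval, possibly unbounded on either side."""

    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"empty interval [{self.lo}, {self.hi}]")

    def intersect(self, other: "Interval") -> "Interval":
        return Interval(max(self.lo, other.lo), min(self.hi, other.hi))

    def contains(self, v: float) -> bool:
        return self.lo <= v <= self.hi

    @property
    def bounded(self) -> bool:
        return math.isfinite(self.lo) and math.isfinite(self.hi)


REAL_LINE = Interval()


@dataclass(frozen=True)
class RelationshipFunction:
    """The function f with I_Y = f(I_X), plus the metadata the likelihood
    integrals need.

    Attributes
    ----------
    forward
        Vectorised map f from X-information to Y-information.
    derivative
        Vectorised f'; required for the change-of-variables form of the
        likelihood's second branch.
    inverse
        f⁻¹ on ``range_`` where one exists, else ``None`` (non-monotone
        maps such as the full-line sinusoid).
    domain, range_
        Intervals that f maps between; integration limits are clipped to
        them.
    label
        Human-readable description used in reports.
    params
        Named numeric parameters (slope, intercept, ...).
    """

    forward: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray] | None = None
    domain: Interval = REAL_LINE
    range_: Interval = REAL_LINE
    label: str = "custom"
    params: dict[str, float] = field(default_factory=dict)

    @property
    def invertible(self) -> bool:
        return self.inverse is not None

    def __call__(self, v: np.ndarray | float) -> np.ndarray | float:
        return self.forward(np.asarray(v, dtype=float))


def identity_function() -> RelationshipFunction:
    return RelationshipFunction(
        forward=lambda v: v,
        derivative=lambda v: np.ones_like(np.asarray(v, dtype=float)),
        inverse=lambda v: v,
        label="identity",
    )


def _linear(slope: float, intercept: float) -> RelationshipFunction:
    slope = float(slope)
    intercept = float(intercept)
    invertible = abs(slope) > FLAT_SLOPE_TOL
    return RelationshipFunction(
        forward=lambda v, s=slope, b=intercept: s * v + b,
        derivative=lambda v, s=slope: np.full_like(
            np.asarray(v, dtype=float), s
        ),
        inverse=(
            (lambda v, s=slope, b=intercept: (v - b) / s) if invertible else None
        ),
        range_=REAL_LINE if invertible else Interval(intercept, intercept),
        label=f"linear(slope={slope:g}, intercept={intercept:g})",
        params={"slope": slope, "intercept": intercept},
    )


def _quadratic(scale: float, restricted: bool) -> RelationshipFunction:
    # Default restricts the domain to the non-negative branch so an exact
    # inverse exists; restricted=False keeps the symmetric full-line
    # parabola, which has no inverse and exercises the preimage-branch
    # handling in the likelihood.  scale < 0 flips the range.
    scale = float(scale)
    if scale == 0.0:
        raise ValueError("quadratic scale must be nonzero")
    rng = Interval(0.0, math.inf) if scale > 0 else Interval(-math.inf, 0.0)
    if restricted:
        return RelationshipFunction(
            forward=lambda v, a=scale: a * v * v,
            derivative=lambda v, a=scale: 2.0 * a * np.asarray(v, dtype=float),
            inverse=lambda v, a=scale: np.sqrt(np.asarray(v, dtype=float) / a),
            domain=Interval(0.0, math.inf),
            range_=rng,
            label=f"quadratic(scale={scale:g}, restricted)",
            params={"scale": scale},
        )
    return RelationshipFunction(
        forward=lambda v, a=scale: a * v * v,
        derivative=lambda v, a=scale: 2.0 * a * np.asarray(v, dtype=float),
        inverse=None,
        range_=rng,
        label=f"quadratic(scale={scale:g})",
        params={"scale": scale},
    )


def _cubic(scale: float) -> RelationshipFunction:
    scale = float(scale)
    if scale == 0.0:
        raise ValueError("cubic scale must be nonzero")
    return RelationshipFunction(
        forward=lambda v, a=scale: a * v**3,
        derivative=lambda v, a=scale: 3.0 * a * np.asarray(v, dtype=float) ** 2,
        inverse=lambda v, a=scale: np.cbrt(np.asarray(v, dtype=float) / a),
        label=f"cubic(scale={scale:g})",
        params={"scale": scale},
    )


def _exponential(rate: float) -> RelationshipFunction:
    rate = float(rate)
    if rate == 0.0:
        raise ValueError("exponential rate must be nonzero")
    return RelationshipFunction(
        forward=lambda v, k=rate: np.exp(k * v),
        derivative=lambda v, k=rate: k * np.exp(k * np.asarray(v, dtype=float)),
        inverse=lambda v, k=rate: np.log(np.asarray(v, dtype=float)) / k,
        range_=Interval(0.0, math.inf),
        label=f"exponential(rate={rate:g})",
        params={"rate": rate},
    )


def _sinusoidal(frequency: float, restricted: bool) -> RelationshipFunction:
    freq = float(frequency)
    if freq == 0.0:
        raise ValueError("sinusoidal frequency must be nonzero")
    if restricted:
        # One monotone branch: domain limited to a half-period around 0.
        half = math.pi / (2.0 * abs(freq))
        return RelationshipFunction(
            forward=lambda v, w=freq: np.sin(w * v),
            derivative=lambda v, w=freq: w * np.cos(w * np.asarray(v, dtype=float)),
            inverse=lambda v, w=freq: np.arcsin(np.asarray(v, dtype=float)) / w,
            domain=Interval(-half, half),
            range_=Interval(-1.0, 1.0),
            label=f"sinusoidal(frequency={freq:g}, restricted)",
            params={"frequency": freq},
        )
    return RelationshipFunction(
        forward=lambda v, w=freq: np.sin(w * v),
        derivative=lambda v, w=freq: w * np.cos(w * np.asarray(v, dtype=float)),
        inverse=None,
        range_=Interval(-1.0, 1.0),
        label=f"sinusoidal(frequency={freq:g})",
        params={"frequency": freq},
    )


BUILTIN_FUNCTIONS = (
    "identity",
    "linear",
    "quadratic",
    "cubic",
    "exponential",
    "sinusoidal",
)


def builtin_function(name: str, **params: float) -> RelationshipFunction:
    """Look up a relationship function from the shipped library.

    Supported names and parameters:

    ==============  ==================================  ==================
    name            parameters (defaults)               inverse
    ==============  ==================================  ==================
    identity        —                                   global
    linear          slope (1), intercept (0)            global if slope≠0
    quadratic       scale (1), restricted (True)        non-negative branch
                                                        (domain [0, ∞));
                                                        none if unrestricted
    cubic           scale (1)                           global
    exponential     rate (1)                            global (range (0, ∞))
    sinusoidal      frequency (1), restricted (False)   only restricted
    ==============  ==================================  ==================
    """
    if name == "identity":
        return identity_function()
    if name == "linear":
        return _linear(params.pop("slope", 1.0), params.pop("intercept", 0.0))
    if name == "quadratic":
        return _quadratic(
            params.pop("scale", 1.0), bool(params.pop("restricted", True))
        )
    if name == "cubic":
        return _cubic(params.pop("scale", 1.0))
    if name == "exponential":
        return _exponential(params.pop("rate", 1.0))
    if name == "sinusoidal":
        return _sinusoidal(
            params.pop("frequency", 1.0), bool(params.pop("restricted", False))
        )
    raise ValueError(
        f"unknown relationship function {name!r}; "
        f"available: {', '.join(BUILTIN_FUNCTIONS)}"
    )


def fit_linear_relationship(
    x: np.ndarray, y: np.ndarray
) -> RelationshipFunction:
    """Ordinary least squares fit of y on x as the relationship estimate.

    Returns a linear :class:`RelationshipFunction` with the exact analytic
    inverse ``(v - intercept) / slope``.  A slope indistinguishable from
    zero yields a function with no inverse, which routes the likelihood's
    second branch through its change-of-variables handling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 points to fit a line")
    if np.var(x) == 0.0:
        raise ValueError("x is constant: linear regression is degenerate")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    return _linear(float(slope), float(intercept))
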