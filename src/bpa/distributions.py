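"""Component distributions and the information/noise variance split.

Each observed variable is modelled as the sum of a latent *information*
component and a latent *noise* component.  After standardising the observed
series to zero mean and unit variance, a single proportion ``alpha`` in
(0, 1) fixes both component variances: the information component carries
``alpha`` of the unit variance and the noise component the remaining
``1 - alpha``.  Only the normal family ships by default, but any family
that can evaluate a density and report a variance plugs in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ComponentDistribution",
    "VariableModel",
    "normalize_series",
    "density",
    "make_variable_model",
]

#: Number of standard deviations beyond which a component density is
#: treated as zero when forming integration limits (normal tail < 1e-22).
TAIL_SDS = 10.0

#: Floor applied to likelihoods before taking logarithms.
LIKELIHOOD_FLOOR = 1e-300


@dataclass(frozen=True)
class ComponentDistribution:
    """A zero-centred component distribution of one latent variable.

    Parameters
    ----------
    family
        Distribution family label.  ``"normal"`` is the only built-in;
        other families must supply ``density_fn``.
    mean
        Location of the component.  Normalisation absorbs the observed
        mean, so component means are zero in normal use.
    variance
        Spread of the component; must be positive for density evaluation.
    density_fn
        Optional callable ``f(v) -> density`` overriding the built-in
        family density (the extension point for non-normal components).
    """

    family: str = "normal"
    mean: float = 0.0
    variance: float = 1.0
    density_fn: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")
        if self.family != "normal" and self.density_fn is None:
            raise ValueError(
                f"family {self.family!r} requires an explicit density_fn"
            )

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def pdf(self, v: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the density at ``v`` (scalar or array)."""
        if self.variance == 0:
            raise ValueError("point-mass component (variance 0) has no density")
        if self.density_fn is not None:
            return self.density_fn(np.asarray(v, dtype=float))
        z = (np.asarray(v, dtype=float) - self.mean) / self.sd
        return np.exp(-0.5 * z * z) / (self.sd * np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class VariableModel:
    """Information/noise decomposition of one standardised variable.

    ``info.variance + noise.variance == 1`` and both means are zero, so
    the marginal of the observed (standardised) variable under the normal
    family is exactly standard normal regardless of the split.
    """

    alpha: float
    info: ComponentDistribution
    noise: ComponentDistribution

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        total = self.info.variance + self.noise.variance
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"component variances must sum to 1, got {total}"
            )
        if self.info.mean != 0.0 or self.noise.mean != 0.0:
            raise ValueError("component means must be 0 after normalization")


def make_variable_model(alpha: float) -> VariableModel:
    """Build the normal-family model for a given information proportion.

    Parameters
    ----------
    alpha
        Proportion of the unit variance attributed to information,
        strictly inside (0, 1).  The endpoints are excluded: a pure-noise
        or pure-information variable makes one component a point mass and
        the likelihoods degenerate.
    """
    alpha = float(alpha)
    if not (0.0 < alpha < 1.0):
        raise ValueError(
            f"alpha must lie strictly in (0, 1); got {alpha}. "
            "Grid values are conventionally clamped to [0.01, 0.99]."
        )
    return VariableModel(
        alpha=alpha,
        info=ComponentDistribution("normal", 0.0, alpha),
        noise=ComponentDistribution("normal", 0.0, 1.0 - alpha),
    )


def normalize_series(values: np.ndarray) -> np.ndarray:
    """Standardise a series to mean 0 and unit population variance.

    Uses the population (divide-by-n) variance so that the "total variance
    equals 1" identity holds exactly on the sample and the alpha
    proportions partition the observed variance.

    Raises
    ------
    ValueError
        If the series has fewer than 2 values, contains non-finite
        entries, or is constant (zero variance).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise ValueError(f"need at least 2 values to normalize, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains NaN or infinite values")
    var = float(np.var(arr))  # population convention
    if var <= 0.0 or not np.isfinite(var):
        raise ValueError("zero variance: constant series cannot be normalized")
    return (arr - arr.mean()) / np.sqrt(var)


def density(dist: ComponentDistribution, v: float) -> float:
    """Probability density of ``dist`` at the point ``v``."""
    return float(dist.pdf(float(v)))
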