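"""Sequential Bayesian updating of the association posterior.

Starting from equal priors on the association hypothesis H1 and the
independence hypothesis H2 (adjustable when prior knowledge exists), each
datapoint's likelihood pair updates the posterior, which becomes the
prior for the next point.  The final posterior probability of H1 is the
Bayesian Probability of Association (BPA), always conditional on the
relationship function the likelihoods were computed with.

The iteration is carried out in log-odds space: the final log-odds equal
logit(prior) plus the sum of per-point log likelihood ratios, which is
mathematically identical to the probability-space recursion but immune
to underflow when a hundred strongly-informative points compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _expit

from .distributions import make_variable_model
from .likelihood import DEFAULT_QUAD_ORDER, likelihood_vectors
from .relationship import RelationshipFunction

__all__ = ["HypothesisState", "BPAResult", "update", "compute_bpa"]

logger = logging.getLogger(__name__)

#: Observed variance this far from 1 on un-flagged input triggers a
#: warning that the series does not look standardised.
_VARIANCE_WARN_TOL = 0.2


@dataclass(frozen=True)
class HypothesisState:
    """Current probabilities of the two hypotheses; always sum to 1."""

    p1: float
    p2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ValueError(f"probabilities out of [0,1]: ({self.p1}, {self.p2})")
        if abs(self.p1 + self.p2 - 1.0) > 1e-9:
            raise ValueError(f"p1 + p2 must equal 1, got {self.p1 + self.p2}")


@dataclass(frozen=True)
class BPAResult:
    """Outcome of one BPA computation at fixed (alpha_x, alpha_y, f)."""

    bpa: float
    n_used: int
    alpha_x: float
    alpha_y: float
    relationship: str
    trajectory: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.bpa <= 1.0):
            raise ValueError(f"bpa out of [0,1]: {self.bpa}")


def update(state: HypothesisState, l1: float, l2: float) -> HypothesisState:
    """One Bayesian update from a datapoint's likelihood pair.

    new_p1 = p1·l1 / (p1·l1 + p2·l2), new_p2 the complement — the exact
    two-hypothesis posterior; renormalised so p1 + p2 = 1 holds exactly.
    """
    if l1 < 0 or l2 < 0:
        raise ValueError("likelihoods must be non-negative")
    denom = state.p1 * l1 + state.p2 * l2
    if denom <= 0.0:
        raise ZeroDivisionError(
            "both weighted likelihoods are zero; apply the likelihood floor "
            "before updating"
        )
    p1 = state.p1 * l1 / denom
    return HypothesisState(p1=p1, p2=1.0 - p1)


def _logit(p: float) -> float:
    # ±inf for the degenerate priors 0 and 1, which are absorbing.
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def compute_bpa(
    x: np.ndarray,
    y: np.ndarray,
    alpha_x: float,
    alpha_y: float,
    f: RelationshipFunction,
    *,
    prior_h1: float = 0.5,
    keep_trajectory: bool = False,
    branch_mode: str = "sum",
    order: int = DEFAULT_QUAD_ORDER,
) -> BPAResult:
    """Bayesian Probability of Association for one (alpha_x, alpha_y, f).

    Parameters
    ----------
    x, y
        Equal-length standardised series (mean 0, unit variance); a
        warning is logged if the variance looks far from 1.  NaN or
        infinite entries are rejected — silently dropping points would
        change the evidence total.
    alpha_x, alpha_y
        Assumed information-variance proportions, strictly in (0, 1).
    f
        Relationship function; the returned probability is conditional
        on this choice of f.
    prior_h1
        Prior probability of association (default 0.5, equal priors).
        Degenerate priors 0 and 1 are absorbing by construction.
    keep_trajectory
        Record the posterior after each datapoint (in input order).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError(f"need at least 2 datapoints, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("input contains NaN or infinite values; no imputation")
    if not (0.0 <= prior_h1 <= 1.0):
        raise ValueError(f"prior_h1 must lie in [0,1], got {prior_h1}")
    for name, arr in (("x", x), ("y", y)):
        var = float(np.var(arr))
        if abs(var - 1.0) > _VARIANCE_WARN_TOL:
            logger.warning(
                "%s has variance %.3g, far from 1: did you forget to normalize?",
                name,
                var,
            )

    mx = make_variable_model(alpha_x)
    my = make_variable_model(alpha_y)
    l1, l2 = likelihood_vectors(
        x, y, mx, my, f, branch_mode=branch_mode, order=order
    )
    log_ratios = np.log(l1) - np.log(l2)
    # Floored pairs on both floors carry no evidence.
    log_ratios[(l1 <= 1e-299) & (l2 <= 1e-299)] = 0.0

    z0 = _logit(prior_h1)
    z_final = z0 + float(np.sum(log_ratios))
    trajectory = None
    if keep_trajectory:
        trajectory = np.asarray(_expit(z0 + np.cumsum(log_ratios)), dtype=float)

    return BPAResult(
        bpa=float(_expit(z_final)),
        n_used=int(x.size),
        alpha_x=float(alpha_x),
        alpha_y=float(alpha_y),
        relationship=f.label,
        trajectory=trajectory,
    )
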