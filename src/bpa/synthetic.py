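"""Synthetic benchmark pairs with known ground truth.

Each generated variable is the sum of a latent information draw and an
independent noise draw.  Associated pairs share one information series
(pushed through the relationship function for the second variable);
unassociated pairs draw the two information series independently.  Noise
variances are scaled so that a chosen proportion ``alpha`` of each
variable's variance is informational, and both observed series are
standardised before being returned — exactly the regime the estimator
assumes.

These generators are the package's primary test fixture: the benchmark
suites reproduce the associated/unassociated grid design (n = 100 per
pair, identity relationship, proportions from 0.01 to 0.99 in steps of
0.15) and the non-linear design in which the noise variance is half the
information variance (alpha = 2/3).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .distributions import TAIL_SDS, normalize_series
from .relationship import (
    Interval,
    RelationshipFunction,
    builtin_function,
    identity_function,
)

__all__ = [
    "SyntheticPair",
    "generate_pair",
    "generate_grid_suite",
    "generate_nonlinear_suite",
    "nonlinear_function_library",
    "standardized_relationship",
    "GRID_SUITE_ALPHAS",
    "DEFAULT_N_POINTS",
]

#: Default number of datapoints per synthetic pair.
DEFAULT_N_POINTS = 100

#: Information proportions of the benchmark grid suite: 0.01 to 0.99 at
#: a gap of 0.15 (seven values, 0.01 ... 0.91).
GRID_SUITE_ALPHAS = tuple(np.round(0.01 + 0.15 * np.arange(7), 10))

_MASK_31 = (1 << 31) - 1


@dataclass(frozen=True)
class SyntheticPair:
    """One generated (x, y) pair with its ground truth."""

    x: np.ndarray
    y: np.ndarray
    truth_alpha_x: float
    truth_alpha_y: float
    associated: bool
    relationship: RelationshipFunction
    seed: int

    @property
    def n(self) -> int:
        return int(self.x.size)


def _truncated_standard_normal(
    rng: np.random.Generator, n: int, f: RelationshipFunction
) -> np.ndarray:
    """Standard-normal information draws, restricted to f's domain.

    Unbounded domains use plain draws; a restricted domain (quadratic's
    non-negative branch, the one-branch sinusoid) uses inverse-CDF
    sampling of the truncated standard normal.
    """
    from scipy import stats

    lo, hi = f.domain.lo, f.domain.hi
    if np.isinf(lo) and np.isinf(hi):
        return rng.standard_normal(n)
    a = stats.norm.cdf(lo) if np.isfinite(lo) else 0.0
    b = stats.norm.cdf(hi) if np.isfinite(hi) else 1.0
    return stats.norm.ppf(a + (b - a) * rng.random(n))


def _info_moments(f: RelationshipFunction) -> tuple[float, float, float, float]:
    """Population means and variances of (I, f(I)) for I standard normal
    truncated to f's domain, by Gauss–Legendre quadrature.

    Returns (mean_i, var_i, mean_fi, var_fi).
    """
    from scipy import stats

    lo = max(f.domain.lo, -TAIL_SDS)
    hi = min(f.domain.hi, TAIL_SDS)
    t, w = np.polynomial.legendre.leggauss(400)
    half = 0.5 * (hi - lo)
    i = lo + half * (t + 1.0)
    dens = stats.norm.pdf(i)
    mass = float(np.sum(w * dens) * half)
    dens = dens / mass  # truncated-normal density
    fi = np.asarray(f.forward(i), dtype=float)

    def moments(v: np.ndarray) -> tuple[float, float]:
        m = float(np.sum(w * dens * v) * half)
        m2 = float(np.sum(w * dens * v * v) * half)
        return m, m2 - m * m

    mean_i, var_i = moments(i)
    mean_fi, var_fi = moments(fi)
    return mean_i, var_i, mean_fi, var_fi


def standardized_relationship(
    f: RelationshipFunction, alpha_x: float, alpha_y: float
) -> RelationshipFunction:
    """The relationship linking the *standardised* information components.

    A pair built from raw components I and f(I) is standardised before
    analysis, so the information components of the standardised series
    are affine transforms of I and f(I).  They are linked not by f but
    by its affine conjugate

        g(u) = (f(s_x·u + m_i) − m_f) / s_y,

    where m_i, m_f are the population means of I and f(I) (I standard
    normal truncated to f's domain), s_x = sqrt(Var I / alpha_x) is the
    population SD of the raw first variable, and s_y = sqrt(Var f(I) /
    alpha_y) that of the second.  Scanning standardised data with g is
    what "using the correct relationship function" means; scanning with
    a conjugate of the wrong f is the mismatched case.
    """
    mean_i, var_i, mean_fi, var_fi = _info_moments(f)
    if var_i <= 0 or var_fi <= 0:
        raise ValueError(f"degenerate information variance for {f.label}")
    s_x = float(np.sqrt(var_i / alpha_x))
    s_y = float(np.sqrt(var_fi / alpha_y))

    def fwd(u, f=f, s_x=s_x, s_y=s_y, m_i=mean_i, m_f=mean_fi):
        return (np.asarray(f.forward(s_x * u + m_i), dtype=float) - m_f) / s_y

    def deriv(u, f=f, s_x=s_x, s_y=s_y, m_i=mean_i):
        return np.asarray(f.derivative(s_x * u + m_i), dtype=float) * (s_x / s_y)

    inv = None
    if f.inverse is not None:
        def inv(v, f=f, s_x=s_x, s_y=s_y, m_i=mean_i, m_f=mean_fi):
            return (np.asarray(f.inverse(s_y * v + m_f), dtype=float) - m_i) / s_x

    def _map_interval(iv: Interval, scale: float, shift: float) -> Interval:
        lo = (iv.lo - shift) / scale if np.isfinite(iv.lo) else iv.lo
        hi = (iv.hi - shift) / scale if np.isfinite(iv.hi) else iv.hi
        return Interval(lo, hi)

    return RelationshipFunction(
        forward=fwd,
        derivative=deriv,
        inverse=inv,
        domain=_map_interval(f.domain, s_x, mean_i),
        range_=_map_interval(f.range_, s_y, mean_fi),
        label=f"standardized[{f.label}; alpha_x={alpha_x:g}, alpha_y={alpha_y:g}]",
        params=dict(f.params),
    )


def generate_pair(
    n: int,
    alpha_x: float,
    alpha_y: float,
    associated: bool,
    f: RelationshipFunction | None = None,
    seed: int = 0,
) -> SyntheticPair:
    """Generate one standardised pair with known information proportions.

    Associated pairs share a single information draw I: the first
    variable observes I plus noise, the second observes f(I) plus noise.
    Unassociated pairs use two independent information draws.  Noise
    variances equal ``info_variance · (1 − alpha) / alpha`` per variable
    so that alpha is the population proportion of informational variance
    (for the identity relationship this is the plain
    ``(1 − alpha) / alpha`` construction, and the population correlation
    of the standardised pair is sqrt(alpha_x · alpha_y)).
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    for name, a in (("alpha_x", alpha_x), ("alpha_y", alpha_y)):
        if not (0.0 < a < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1), got {a}")
    if f is None:
        f = identity_function()

    rng = np.random.default_rng(seed)
    _, var_ix, _, var_iy = _info_moments(f)
    if var_ix <= 0 or var_iy <= 0:
        raise ValueError(
            f"relationship {f.label} gives a degenerate information variance"
        )

    i_x = _truncated_standard_normal(rng, n, f)
    if associated:
        i_y = np.asarray(f.forward(i_x), dtype=float)
    else:
        i_y = np.asarray(f.forward(_truncated_standard_normal(rng, n, f)), dtype=float)

    sd_nx = np.sqrt(var_ix * (1.0 - alpha_x) / alpha_x)
    sd_ny = np.sqrt(var_iy * (1.0 - alpha_y) / alpha_y)
    x = i_x + sd_nx * rng.standard_normal(n)
    y = i_y + sd_ny * rng.standard_normal(n)

    return SyntheticPair(
        x=normalize_series(x),
        y=normalize_series(y),
        truth_alpha_x=float(alpha_x),
        truth_alpha_y=float(alpha_y),
        associated=bool(associated),
        relationship=f,
        seed=int(seed),
    )


def _pair_seeds(master_seed: int, count: int) -> np.ndarray:
    """Per-pair seeds from a master seed.

    Splitting rule: the 32-bit state stream of
    ``np.random.SeedSequence(master_seed)``, masked to 31 bits — stable
    across runs and platforms, independent between pairs.
    """
    state = np.random.SeedSequence(master_seed).generate_state(count)
    return state & _MASK_31


def generate_grid_suite(
    seed: int,
    alphas: tuple[float, ...] = GRID_SUITE_ALPHAS,
    n: int = DEFAULT_N_POINTS,
) -> list[SyntheticPair]:
    """The benchmark grid suite: one associated and one unassociated
    identity-relationship pair of ``n`` points for every (alpha_x,
    alpha_y) combination.

    The default grid has seven proportions per axis (0.01 to 0.99 at a
    gap of 0.15), i.e. 49 combinations and 98 pairs.  Iteration order is
    alpha_x-major, alpha_y-minor, associated before unassociated.
    """
    combos = [(ax, ay) for ax in alphas for ay in alphas]
    seeds = _pair_seeds(seed, 2 * len(combos))
    f = identity_function()
    pairs: list[SyntheticPair] = []
    for k, (ax, ay) in enumerate(combos):
        pairs.append(generate_pair(n, ax, ay, True, f, int(seeds[2 * k])))
        pairs.append(generate_pair(n, ax, ay, False, f, int(seeds[2 * k + 1])))
    return pairs


def nonlinear_function_library() -> list[RelationshipFunction]:
    """The five non-identity relationship functions of the non-linear
    benchmark: decreasing linear, full-line quadratic (the symmetric
    parabola, no inverse), cubic, exponential, and the full-line
    sinusoid (no inverse).  The members are chosen for shape diversity —
    decreasing affine, symmetric even, odd with steep tails, convex
    monotone, bounded oscillatory — so that assuming the wrong member is
    a genuinely different model; the two non-monotone members are the
    cases where rank and product-moment correlations collapse while the
    association is exact.
    """
    return [
        builtin_function("linear", slope=-2.0, intercept=1.0),
        builtin_function("quadratic", restricted=False),
        builtin_function("cubic"),
        builtin_function("exponential"),
        builtin_function("sinusoidal"),
    ]


def generate_nonlinear_suite(
    n: int = DEFAULT_N_POINTS, seed: int = 0
) -> list[SyntheticPair]:
    """One associated pair per non-identity relationship function, with
    the noise variance of each variable equal to half its information
    variance (alpha = 2/3 on both sides).

    Each returned pair's ``relationship`` is the affine conjugate of its
    generating function in standardised coordinates (see
    :func:`standardized_relationship`): that is the function a correct
    analysis of the standardised data must supply.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    funcs = nonlinear_function_library()
    seeds = _pair_seeds(seed, len(funcs))
    alpha = 2.0 / 3.0
    pairs = []
    for f, s in zip(funcs, seeds):
        pair = generate_pair(n, alpha, alpha, True, f, int(s))
        pairs.append(
            dataclasses.replace(
                pair, relationship=standardized_relationship(f, alpha, alpha)
            )
        )
    return pairs
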