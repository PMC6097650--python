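"""Grid scan over information proportions, association call, and
causal-direction scores.

The information proportions of the two variables are rarely known, so
the BPA is evaluated over a grid of assumed proportions (alpha'_x,
alpha'_y).  A pair is called associated when any grid cell's posterior
reaches a near-one threshold.  Because the posterior collapses towards 0
once an assumed proportion exceeds the true one, the BPA-weighted sums

    S_X = Σ_cells alpha'_x · BPA,    S_Y = Σ_cells alpha'_y · BPA

compare the information content of the two variables: the variable
supporting association at higher assumed proportions scores higher and —
since an effect inherits its cause's noise on top of its own — is
inferred to be the cause.  Near-equal scores (saturated grids) leave the
direction undetermined.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .bayes import compute_bpa
from .likelihood import DEFAULT_QUAD_ORDER
from .relationship import RelationshipFunction

__all__ = [
    "AlphaGrid",
    "BPAScanResult",
    "scan_alphas",
    "call_association",
    "causal_scores",
    "DEFAULT_ASSOCIATION_THRESHOLD",
    "DIRECTION_TIE_TOL",
]

#: The association call approximates "posterior of 1"; configurable.
DEFAULT_ASSOCIATION_THRESHOLD = 0.99

#: Relative |S_X − S_Y| below which the direction is undetermined.
DIRECTION_TIE_TOL = 0.01

#: Grid values are clamped to this closed interval (alpha endpoints are
#: excluded from the model).
_ALPHA_CLAMP = (0.01, 0.99)


def _validate_values(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    arr = np.clip(arr, *_ALPHA_CLAMP)
    if np.any(np.diff(arr) <= 0):
        raise ValueError(f"{name} must be strictly increasing after clamping")
    return arr


@dataclass(frozen=True)
class AlphaGrid:
    """Grid of assumed information proportions for the two variables."""

    values_x: np.ndarray
    values_y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values_x", _validate_values(self.values_x, "values_x"))
        object.__setattr__(self, "values_y", _validate_values(self.values_y, "values_y"))

    @classmethod
    def real_data(cls) -> "AlphaGrid":
        """9×9 grid from 0.1 to 0.9 in steps of 0.1 (real-data protocol)."""
        v = np.round(np.arange(1, 10) * 0.1, 10)
        return cls(v, v.copy())

    @classmethod
    def synthetic(cls) -> "AlphaGrid":
        """7×7 grid from 0.01 to 0.99 in steps of 0.15 (synthetic protocol:
        0.01, 0.16, ..., 0.91)."""
        v = np.round(0.01 + 0.15 * np.arange(7), 10)
        return cls(v, v.copy())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values_x.size, self.values_y.size


@dataclass(frozen=True)
class BPAScanResult:
    """BPA over a grid plus the association call and direction scores.

    ``bpa_matrix[i, j]`` is the posterior at ``values_x[i], values_y[j]``.
    """

    grid: AlphaGrid
    bpa_matrix: np.ndarray
    associated: bool
    threshold: float
    s_x: float
    s_y: float
    predicted_direction: str
    relationship: str = "identity"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.bpa_matrix, dtype=float)
        if m.shape != self.grid.shape:
            raise ValueError(f"matrix shape {m.shape} != grid shape {self.grid.shape}")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("BPA matrix entries must lie in [0, 1]")
        object.__setattr__(self, "bpa_matrix", m)

    @property
    def max_bpa(self) -> float:
        return float(self.bpa_matrix.max())

    def to_csv(self) -> str:
        """Heatmap as CSV: rows are alpha'_x, columns alpha'_y, with the
        grid values in the header row and first column."""
        buf = io.StringIO()
        header = ",".join(["alpha_x\\alpha_y"] + [f"{v:g}" for v in self.grid.values_y])
        buf.write(header + "\n")
        for i, ax in enumerate(self.grid.values_x):
            row = ",".join(
                [f"{ax:g}"] + [f"{v:.12g}" for v in self.bpa_matrix[i]]
            )
            buf.write(row + "\n")
        return buf.getvalue()

    def to_dict(self) -> dict:
        return {
            "alpha_x_values": self.grid.values_x.tolist(),
            "alpha_y_values": self.grid.values_y.tolist(),
            "bpa_matrix": self.bpa_matrix.tolist(),
            "associated": bool(self.associated),
            "threshold": self.threshold,
            "s_x": self.s_x,
            "s_y": self.s_y,
            "predicted_direction": self.predicted_direction,
            "relationship": self.relationship,
            "max_bpa": self.max_bpa,
        }


def _direction(s_x: float, s_y: float, tie_tol: float) -> str:
    top = max(s_x, s_y)
    if top <= 0.0 or abs(s_x - s_y) / top < tie_tol:
        return "undetermined"
    return "x_causes_y" if s_x > s_y else "y_causes_x"


def causal_scores(
    bpa_matrix: "np.ndarray | BPAScanResult",
    grid: AlphaGrid | None = None,
    *,
    tie_tol: float = DIRECTION_TIE_TOL,
) -> tuple[float, float, str]:
    """BPA-weighted direction scores and the direction call.

    Both scores are double sums over the full grid; the variable with
    the larger score is inferred to carry more information and hence to
    be the cause.  Accepts either a completed :class:`BPAScanResult` or
    an explicit (matrix, grid) pair.
    """
    if isinstance(bpa_matrix, BPAScanResult):
        grid = bpa_matrix.grid
        bpa_matrix = bpa_matrix.bpa_matrix
    if grid is None:
        raise ValueError("grid is required when passing a bare matrix")
    m = np.asarray(bpa_matrix, dtype=float)
    s_x = float(np.sum(grid.values_x[:, None] * m))
    s_y = float(np.sum(grid.values_y[None, :] * m))
    return s_x, s_y, _direction(s_x, s_y, tie_tol)


def call_association(
    bpa_matrix: "np.ndarray | BPAScanResult",
    threshold: float = DEFAULT_ASSOCIATION_THRESHOLD,
) -> bool:
    """True iff any grid cell's posterior reaches the threshold."""
    if isinstance(bpa_matrix, BPAScanResult):
        bpa_matrix = bpa_matrix.bpa_matrix
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    return bool(np.asarray(bpa_matrix).max() >= threshold)


def scan_alphas(
    x: np.ndarray,
    y: np.ndarray,
    f: RelationshipFunction,
    grid: AlphaGrid | None = None,
    *,
    threshold: float = DEFAULT_ASSOCIATION_THRESHOLD,
    tie_tol: float = DIRECTION_TIE_TOL,
    prior_h1: float = 0.5,
    branch_mode: str = "sum",
    order: int = DEFAULT_QUAD_ORDER,
) -> BPAScanResult:
    """Evaluate the BPA on every grid cell and derive the calls.

    Inputs must already be standardised.  Cells are independent, and the
    result is identical regardless of evaluation order.
    """
    if grid is None:
        grid = AlphaGrid.real_data()
    nx, ny = grid.shape
    matrix = np.empty((nx, ny), dtype=float)
    for i, ax in enumerate(grid.values_x):
        for j, ay in enumerate(grid.values_y):
            matrix[i, j] = compute_bpa(
                x,
                y,
                ax,
                ay,
                f,
                prior_h1=prior_h1,
                branch_mode=branch_mode,
                order=order,
            ).bpa
    s_x, s_y, direction = causal_scores(matrix, grid, tie_tol=tie_tol)
    return BPAScanResult(
        grid=grid,
        bpa_matrix=matrix,
        associated=call_association(matrix, threshold),
        threshold=float(threshold),
        s_x=s_x,
        s_y=s_y,
        predicted_direction=direction,
        relationship=f.label,
    )
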