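"""Classical association measures computed alongside the BPA.

Pearson (with two-sided p-value), Spearman and Kendall rank correlations
come from scipy.  Normalized mutual information uses equal-frequency
binning with a plug-in joint-histogram estimator, normalised by the
smaller marginal entropy and clamped to [0, 1].  No single canonical MI
estimator exists for continuous data; this one is simple, reproducible,
bounded, and detects non-linear dependence — and it is swappable via the
``n_bins`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BaselinePanel",
    "baseline_panel",
    "normalized_mutual_information",
    "default_bin_count",
]


@dataclass(frozen=True)
class BaselinePanel:
    """The comparison measures for one pair of series."""

    pearson: float
    pearson_p: float
    spearman: float
    kendall: float
    nmi: float

    def __post_init__(self) -> None:
        for name in ("pearson", "spearman", "kendall"):
            v = getattr(self, name)
            if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} out of [-1, 1]: {v}")
        if not 0.0 <= self.nmi <= 1.0:
            raise ValueError(f"nmi out of [0, 1]: {self.nmi}")

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "pearson_p": self.pearson_p,
            "spearman": self.spearman,
            "kendall": self.kendall,
            "nmi": self.nmi,
        }


def default_bin_count(n: int) -> int:
    """ceil(sqrt(n / 5)) bins — about 4–5 bins at n = 100, keeping the
    expected count per joint cell high enough for the plug-in estimate."""
    return max(2, math.ceil(math.sqrt(n / 5)))


def _equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value a bin index 0..n_bins-1 with (near-)equal counts."""
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    if np.unique(edges).size < edges.size:
        raise ValueError(
            f"too few distinct values for {n_bins} equal-frequency bins"
        )
    return np.searchsorted(edges, values, side="left")


def normalized_mutual_information(
    x: np.ndarray, y: np.ndarray, n_bins: int | None = None
) -> float:
    """Histogram NMI in [0, 1]: MI(binned x, binned y) / min(H_x, H_y).

    Equal-frequency bins make the marginal entropies near-maximal and
    identical partitions for monotone transforms, so any injective
    deterministic relationship scores 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n_bins is None:
        n_bins = default_bin_count(n)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if n < n_bins:
        raise ValueError(f"n={n} is smaller than n_bins={n_bins}")

    bx = _equal_frequency_bins(x, n_bins)
    by = _equal_frequency_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins), dtype=float)
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))
    h_min = min(stats.entropy(px), stats.entropy(py))
    if h_min <= 0.0:
        return 0.0
    return float(np.clip(mi / h_min, 0.0, 1.0))


def baseline_panel(x: np.ndarray, y: np.ndarray) -> BaselinePanel:
    """Pearson (+p), Spearman, Kendall and NMI for one pair."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("constant input: correlations undefined")

    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    kendall = stats.kendalltau(x, y)
    return BaselinePanel(
        pearson=float(pearson.statistic),
        pearson_p=float(pearson.pvalue),
        spearman=float(spearman.statistic),
        kendall=float(kendall.statistic),
        nmi=normalized_mutual_information(x, y),
    )
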