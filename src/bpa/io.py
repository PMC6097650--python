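"""File input, analysis configuration, and the JSON report.

The full pipeline mirrors the real-data protocol: read a two-column
delimited file, standardise both series, estimate (or accept) the
relationship function, scan the information-proportion grid, call
association, score the causal direction, and attach the classical
baseline measures.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import baseline_panel
from .distributions import normalize_series
from .relationship import (
    RelationshipFunction,
    builtin_function,
    fit_linear_relationship,
)
from .scan import (
    DEFAULT_ASSOCIATION_THRESHOLD,
    AlphaGrid,
    BPAScanResult,
    scan_alphas,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "read_pair_file", "run_analysis"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def read_pair_file(
    path: str | Path,
    delimiter: str = ",",
    columns: tuple[int | str, int | str] = (0, 1),
    has_header: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Read two numeric columns from a delimited text file.

    Columns may be selected by 0-based index or, when ``has_header`` is
    set, by name.  Any non-numeric cell in a selected column aborts with
    an error naming the offending row (1-based, counting data rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    frame = pd.read_csv(
        path,
        sep=delimiter,
        header=0 if has_header else None,
        dtype=str,
        skip_blank_lines=True,
    )
    if frame.shape[1] < 2:
        raise ValueError(
            f"{path}: need at least 2 columns, found {frame.shape[1]}"
        )

    def pick(sel: int | str) -> pd.Series:
        if isinstance(sel, str) and not str(sel).lstrip("-").isdigit():
            if not has_header:
                raise ValueError(
                    f"column selected by name {sel!r} but file has no header"
                )
            if sel not in frame.columns:
                raise ValueError(
                    f"column {sel!r} not found; available: {list(frame.columns)}"
                )
            return frame[sel]
        idx = int(sel)
        if not (0 <= idx < frame.shape[1]):
            raise ValueError(
                f"column index {idx} out of range for {frame.shape[1]} columns"
            )
        return frame.iloc[:, idx]

    def to_float(series: pd.Series, label: int | str) -> np.ndarray:
        out = np.empty(len(series), dtype=float)
        for row, raw in enumerate(series, start=1):
            try:
                out[row - 1] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} in column {label!r} "
                    f"at data row {row}"
                ) from None
        return out

    cx, cy = columns
    x = to_float(pick(cx), cx)
    y = to_float(pick(cy), cy)
    if x.size < 2:
        raise ValueError(f"{path}: need at least 2 data rows, found {x.size}")
    return x, y


@dataclass
class AnalysisConfig:
    """Everything needed to rerun one analysis."""

    path: str
    delimiter: str = ","
    columns: tuple[int | str, int | str] = (0, 1)
    has_header: bool = False
    normalize: bool = True
    #: "fit-linear" or a builtin name (identity, linear, quadratic, ...)
    relationship: str = "fit-linear"
    relationship_params: dict[str, float] = field(default_factory=dict)
    #: "real" (9x9, 0.1..0.9) or "synthetic" (7x7, 0.01..0.91)
    grid: str = "real"
    threshold: float = DEFAULT_ASSOCIATION_THRESHOLD
    prior_h1: float = 0.5
    branch_mode: str = "sum"
    heatmap_csv: str | None = None
    seed: int | None = None


@dataclass
class AnalysisReport:
    """Serializable record of one full analysis.

    The reported BPA values are conditional on the stated relationship
    function.
    """

    schema_version: int
    software_version: str
    input_path: str
    config: dict
    normalization: dict
    relationship: dict
    scan: dict
    baselines: dict
    timestamp: str

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def _resolve_grid(name: str) -> AlphaGrid:
    if name == "real":
        return AlphaGrid.real_data()
    if name == "synthetic":
        return AlphaGrid.synthetic()
    raise ValueError(f"unknown grid {name!r}; use 'real' or 'synthetic'")


def _resolve_relationship(
    config: AnalysisConfig, x: np.ndarray, y: np.ndarray
) -> RelationshipFunction:
    if config.relationship == "fit-linear":
        return fit_linear_relationship(x, y)
    return builtin_function(config.relationship, **config.relationship_params)


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the full pipeline for one input file and build the report."""
    raw_x, raw_y = read_pair_file(
        config.path, config.delimiter, config.columns, config.has_header
    )
    normalization = {
        "applied": bool(config.normalize),
        "x_mean": float(np.mean(raw_x)),
        "x_variance": float(np.var(raw_x)),
        "y_mean": float(np.mean(raw_y)),
        "y_variance": float(np.var(raw_y)),
    }
    if config.normalize:
        x, y = normalize_series(raw_x), normalize_series(raw_y)
    else:
        x, y = np.asarray(raw_x, float), np.asarray(raw_y, float)

    f = _resolve_relationship(config, x, y)
    logger.info("relationship: %s", f.label)
    grid = _resolve_grid(config.grid)
    logger.info("scanning %dx%d proportion grid", *grid.shape)
    result: BPAScanResult = scan_alphas(
        x,
        y,
        f,
        grid,
        threshold=config.threshold,
        prior_h1=config.prior_h1,
        branch_mode=config.branch_mode,
    )
    logger.info(
        "max BPA %.3f; associated=%s; direction=%s",
        result.max_bpa,
        result.associated,
        result.predicted_direction,
    )
    panel = baseline_panel(x, y)

    if config.heatmap_csv:
        Path(config.heatmap_csv).write_text(result.to_csv())
        logger.info("heatmap written to %s", config.heatmap_csv)

    return AnalysisReport(
        schema_version=REPORT_SCHEMA_VERSION,
        software_version=__version__,
        input_path=str(config.path),
        config={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        normalization=normalization,
        relationship={"label": f.label, "params": dict(f.params)},
        scan=result.to_dict(),
        baselines=panel.to_dict(),
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
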