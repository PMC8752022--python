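"""Performance indicators aggregated from replicate-level RTE scores.

Five indicators per catchment area plus a global (whole-ecosystem) row:

* mean RTE over replicates and scenarios;
* P(RTE > 0.75), the fraction of replicate x scenario scores above 0.75;
* RTE error, the standard error of the replicate-mean RTE;
* stability (%), how insensitive scores are to the sampled data
  perturbations: per area x scenario, the share of replicates within
  +/- delta of the replicate median, averaged;
* Shannon entropy (%) of the replicate score distribution, binned over
  [0, 1] and normalized by the feasible maximum ln(n_bins) — 0% means every
  replicate lands in one bin (homogeneous management), 100% means the bins
  are filled uniformly.

Even-length medians use the lower middle order statistic, a fixed
convention so stability is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .montecarlo import MonteCarloResult

__all__ = [
    "GLOBAL_ROW",
    "PerformanceReport",
    "ComparisonReport",
    "mean_rte",
    "prob_rte_above",
    "rte_error",
    "stability",
    "shannon_entropy",
    "build_report",
    "compare",
]

GLOBAL_ROW = "GLOBAL"
INDICATOR_COLUMNS = ("mean_rte", "prob_above", "rte_error", "stability_pct", "entropy_pct")


def _block(result: MonteCarloResult, orientation: str, area_id: str | None) -> np.ndarray:
    """Scores with replicate axis first: (R, S) for an area, (R, S, A) globally."""
    block = result.scores_for(orientation, area_id)
    if block.size == 0:
        raise ValueError("empty score set")
    return block


def mean_rte(result: MonteCarloResult, orientation: str = "input", area_id: str | None = None) -> float:
    """Arithmetic mean over replicates and scenarios (and areas, globally)."""
    return float(_block(result, orientation, area_id).mean())


def prob_rte_above(
    result: MonteCarloResult,
    threshold: float = 0.75,
    orientation: str = "input",
    area_id: str | None = None,
) -> float:
    """Fraction of replicate x scenario scores strictly greater than threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    block = _block(result, orientation, area_id)
    return float((block > threshold).mean())


def rte_error(result: MonteCarloResult, orientation: str = "input", area_id: str | None = None) -> float:
    """Standard error of the replicate-mean RTE (sd of replicate means / sqrt(R))."""
    block = _block(result, orientation, area_id)
    if block.shape[0] < 2:
        raise ValueError("rte_error needs at least 2 replicates")
    rep_means = block.reshape(block.shape[0], -1).mean(axis=1)
    if np.ptp(rep_means) == 0.0:  # exact zero for constant replicate means
        return 0.0
    return float(rep_means.std(ddof=1) / np.sqrt(block.shape[0]))


def _lower_median(sorted_scores: np.ndarray) -> np.ndarray:
    """Median along axis 0 using the lower middle order statistic for even n."""
    n = sorted_scores.shape[0]
    return sorted_scores[(n - 1) // 2]


def stability(
    result: MonteCarloResult,
    delta: float = 0.05,
    orientation: str = "input",
    area_id: str | None = None,
) -> float:
    """Percent of replicates within +/- delta of the replicate median.

    Computed per area x scenario and averaged; 100 when all replicates are
    identical (perturbing the data does not move the score at all).
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    block = _block(result, orientation, area_id)
    if block.shape[0] < 2:
        raise ValueError("stability needs at least 2 replicates")
    med = _lower_median(np.sort(block, axis=0))
    within = np.abs(block - med[None, ...]) <= delta + 1e-12
    return float(100.0 * within.mean())


def shannon_entropy(
    result: MonteCarloResult,
    n_bins: int = 10,
    orientation: str = "input",
    area_id: str | None = None,
    normalize_by_occupied: bool = False,
) -> float:
    """Normalized Shannon entropy (%) of the replicate score distribution.

    Scores are binned into ``n_bins`` equal-width bins over [0, 1] per
    area x scenario; H = -sum p ln p over nonempty bins, reported as
    100 x H / ln(n_bins) and averaged. ``normalize_by_occupied`` switches the
    denominator to ln(#occupied bins) (0 when a single bin is occupied).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    block = _block(result, orientation, area_id)
    if block.ndim == 2:
        block = block[:, :, None]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    r = block.shape[0]
    total = 0.0
    count = 0
    for s in range(block.shape[1]):
        for a in range(block.shape[2]):
            hist, _ = np.histogram(block[:, s, a], bins=edges)
            p = hist[hist > 0] / r
            h = float(-(p * np.log(p)).sum())
            if normalize_by_occupied:
                denom = np.log(len(p)) if len(p) > 1 else np.inf
            else:
                denom = np.log(n_bins)
            total += 100.0 * h / denom if np.isfinite(denom) else 0.0
            count += 1
    return total / count


@dataclass
class PerformanceReport:
    """Indicator table: one row per area plus a single global row."""

    label: str
    orientation: str
    frame: pd.DataFrame  # index: area_id + GLOBAL_ROW; columns: INDICATOR_COLUMNS

    def __post_init__(self) -> None:
        if list(self.frame.columns) != list(INDICATOR_COLUMNS):
            raise ValueError(f"report columns must be {INDICATOR_COLUMNS}")
        if list(self.frame.index).count(GLOBAL_ROW) != 1:
            raise ValueError("report needs exactly one global row")
        f = self.frame
        checks = (
            (f["mean_rte"].between(0, 1) | f["mean_rte"].isna()).all(),
            (f["prob_above"].between(0, 1)).all(),
            (f["rte_error"] >= 0).all(),
            (f["stability_pct"].between(0, 100)).all(),
            (f["entropy_pct"].between(0, 100)).all(),
        )
        if not all(checks):
            raise ValueError("indicator values outside their declared ranges")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="area_id")


def build_report(
    result: MonteCarloResult,
    orientation: str = "input",
    threshold: float = 0.75,
    delta: float = 0.05,
    n_bins: int = 10,
    label: str | None = None,
) -> PerformanceReport:
    """Aggregate a Monte Carlo result into the full indicator table."""
    rows = {}
    for area in [*result.area_ids, None]:
        key = area if area is not None else GLOBAL_ROW
        rows[key] = {
            "mean_rte": mean_rte(result, orientation, area),
            "prob_above": prob_rte_above(result, threshold, orientation, area),
            "rte_error": rte_error(result, orientation, area),
            "stability_pct": stability(result, delta, orientation, area),
            "entropy_pct": shannon_entropy(result, n_bins, orientation, area),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(INDICATOR_COLUMNS))
    return PerformanceReport(label or result.label, orientation, frame)


@dataclass
class ComparisonReport:
    """Pre/post indicator tables plus percent variation per cell.

    Variations are computed on unrounded indicator values (display rounding
    happens only at rendering time); cells with a zero pre value carry NaN as
    the undefined-variation flag.
    """

    pre: PerformanceReport
    post: PerformanceReport
    pct_variation: pd.DataFrame

    def render(self) -> pd.DataFrame:
        """Human-readable table: rounded post values with bracketed variation.

        RTE-scale columns round to 2 decimals, RTE error to 4, percentages
        to 2 — but the bracketed percentages always derive from the
        unrounded indicators.
        """
        decimals = {"mean_rte": 2, "prob_above": 2, "rte_error": 4,
                    "stability_pct": 2, "entropy_pct": 2}
        out = {}
        for col, nd in decimals.items():
            cells = []
            for idx in self.pre.frame.index:
                pre_v = self.pre.frame.loc[idx, col]
                post_v = self.post.frame.loc[idx, col]
                var = self.pct_variation.loc[idx, col]
                bracket = "(n/a)" if pd.isna(var) else f"({var:.2f})"
                cells.append(f"{pre_v:.{nd}f} -> {post_v:.{nd}f}{bracket}")
            out[col] = cells
        return pd.DataFrame(out, index=self.pre.frame.index)

    def to_csv(self, path: str | Path) -> None:
        wide = pd.concat(
            {"pre": self.pre.frame, "post": self.post.frame, "pct_variation": self.pct_variation},
            axis=1,
        )
        wide.columns = [f"{col}_{which}" for which, col in wide.columns]
        wide.to_csv(path, index_label="area_id")


def compare(pre: PerformanceReport, post: PerformanceReport) -> ComparisonReport:
    """Percent variation 100 x (post - pre) / pre per indicator per row."""
    if list(pre.frame.index) != list(post.frame.index):
        raise ValueError("pre and post reports cover different area sets")
    if pre.orientation != post.orientation:
        raise ValueError("pre and post reports use different orientations")
    with np.errstate(divide="ignore", invalid="ignore"):
        var = 100.0 * (post.frame - pre.frame) / pre.frame
    var = var.mask(pre.frame == 0)  # undefined-variation flag
    return ComparisonReport(pre, post, var)
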