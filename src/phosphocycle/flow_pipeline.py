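"""Flow-cytometry analysis stages for poly-transfection data.

Gating of transfected cells, multi-dimensional binning on transfection
markers, per-bin summary statistics, fold-changes, robustness scores,
and the log10-IQR cell-to-cell noise metric.

Conventions (applied uniformly):

* a cell is assigned to a bin iff, in every binned dimension, its value
  is greater than the low edge and less-than-or-equal-to the high edge;
* bins with three or fewer cells are dropped (outliers would dominate);
* non-positive fluorescence values are discarded before computing
  medians or IQRs on binned or gated populations (autofluorescence
  subtraction makes some measured values negative);
* all quantiles use linear interpolation between order statistics;
* across experimental repeats, fold-changes are aggregated as the mean
  of log2 fold-changes, not the log2 of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinGrid",
    "MIN_BIN_COUNT",
    "gate_transfected",
    "positivity_threshold",
    "log_bin_edges",
    "bin_events",
    "summarize_bins",
    "fold_change",
    "mean_log2_fold",
    "robustness",
    "noise_iqr",
]

MIN_BIN_COUNT = 4  # bins with <= 3 cells are ignored


def positivity_threshold(control_values, q: float = 0.999) -> float:
    """Positivity threshold from a negative-control population quantile."""
    vals = np.asarray(control_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("control population is empty")
    return float(np.quantile(vals, q))


def gate_transfected(
    events: pd.DataFrame,
    channels: Sequence[str],
    threshold,
) -> pd.DataFrame:
    """Keep cells positive (above threshold) in ANY of the listed channels.

    ``threshold`` is a scalar applied to every channel or a mapping
    channel -> threshold.  OR semantics: a cell is transfected if it is
    positive for the transfection marker or the output reporter.
    """
    if not channels:
        raise ValueError("need at least one gating channel")
    missing = [c for c in channels if c not in events.columns]
    if missing:
        raise KeyError(f"channels not in events: {missing}")
    keep = np.zeros(len(events), dtype=bool)
    for c in channels:
        thr = threshold[c] if isinstance(threshold, Mapping) else threshold
        keep |= events[c].to_numpy(dtype=float) > thr
    return events.loc[keep]


def log_bin_edges(low_decade: float, high_decade: float, bins_per_decade: int = 6) -> np.ndarray:
    """Log-spaced bin edges from 10**low_decade to 10**high_decade."""
    n_bins = int(round((high_decade - low_decade) * bins_per_decade))
    if n_bins < 1:
        raise ValueError("empty edge range")
    return 10.0 ** np.linspace(low_decade, high_decade, n_bins + 1)


@dataclass(frozen=True)
class BinGrid:
    """Multi-dimensional bin assignment over transfection-marker channels.

    ``assignment`` holds, per cell, a tuple of per-channel bin indices or
    None when the cell falls outside the edges in any dimension.
    ``counts`` maps bin index tuples to cell counts; ``retained`` lists
    the bins that survive the minimum-count rule.
    """

    channels: tuple[str, ...]
    edges: Mapping[str, np.ndarray]
    assignment: np.ndarray = field(repr=False)  # object array of tuples / None
    min_count: int = MIN_BIN_COUNT

    @property
    def counts(self) -> dict[tuple, int]:
        out: dict[tuple, int] = {}
        for a in self.assignment:
            if a is not None:
                out[a] = out.get(a, 0) + 1
        return out

    @property
    def retained(self) -> list[tuple]:
        return sorted(b for b, n in self.counts.items() if n >= self.min_count)

    @property
    def dropped(self) -> list[tuple]:
        return sorted(b for b, n in self.counts.items() if n < self.min_count)

    def members(self, bin_index: tuple) -> np.ndarray:
        """Boolean mask of cells assigned to one bin."""
        return np.array([a == bin_index for a in self.assignment], dtype=bool)

    @property
    def n_assigned(self) -> int:
        return int(sum(a is not None for a in self.assignment))

    @property
    def n_unassigned(self) -> int:
        return len(self.assignment) - self.n_assigned


def bin_events(
    events: pd.DataFrame,
    channels: Sequence[str],
    edges: Mapping[str, Sequence[float]] | Sequence[float],
) -> BinGrid:
    """Assign each cell to a multi-dimensional bin over ``channels``.

    Assignment uses the half-open (low, high] convention in every
    dimension; values at or below the lowest edge, or above the highest,
    are unassigned.  Bins with <= 3 cells are reported as dropped.
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("need at least one binning channel")
    if not isinstance(edges, Mapping):
        edges = {c: edges for c in channels}
    clean: dict[str, np.ndarray] = {}
    for c in channels:
        e = np.asarray(edges[c], dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError(f"edges for {c!r} must be strictly increasing, length >= 2")
        clean[c] = e

    n = len(events)
    idx_per_channel = []
    for c in channels:
        v = events[c].to_numpy(dtype=float)
        e = clean[c]
        # (low, high]: right-closed intervals
        i = np.searchsorted(e, v, side="left") - 1
        ok = (v > e[0]) & (v <= e[-1])
        idx_per_channel.append(np.where(ok, i, -1))
    stacked = np.column_stack(idx_per_channel)
    assigned = np.all(stacked >= 0, axis=1)
    assignment = np.empty(n, dtype=object)
    assignment[:] = None
    for k in np.flatnonzero(assigned):
        assignment[k] = tuple(int(i) for i in stacked[k])
    return BinGrid(channels=channels, edges=clean, assignment=assignment)


def _median_positive(values: np.ndarray) -> tuple[float, int]:
    pos = values[np.isfinite(values) & (values > 0)]
    if pos.size == 0:
        return np.nan, 0
    return float(np.median(pos)), int(pos.size)


def summarize_bins(
    grid: BinGrid,
    events: pd.DataFrame,
    value_channel: str,
) -> pd.DataFrame:
    """Per-retained-bin median and log10-IQR of the value channel.

    Medians and IQRs are computed on positive values only; bins whose
    positive-value count falls to <= 3 after discarding are marked
    undefined (NaN).  Returns a DataFrame indexed by bin tuples with
    columns n, n_positive, median, iqr_log10.
    """
    values = events[value_channel].to_numpy(dtype=float)
    rows = []
    for b in grid.retained:
        mask = grid.members(b)
        med, npos = _median_positive(values[mask])
        if npos < grid.min_count:
            med, iqr = np.nan, np.nan
        else:
            iqr = noise_iqr(values[mask])
        rows.append({"bin": b, "n": int(mask.sum()), "n_positive": npos,
                     "median": med, "iqr_log10": iqr})
    out = pd.DataFrame(rows, columns=["bin", "n", "n_positive", "median", "iqr_log10"])
    return out.set_index("bin")


def fold_change(summary_condition: pd.DataFrame, summary_reference: pd.DataFrame) -> pd.Series:
    """Per-bin fold-change: median(condition) / median(reference).

    Bins with an undefined reference (or condition) median get NaN.
    Summaries must share a bin structure; only common bins are compared.
    """
    common = summary_condition.index.intersection(summary_reference.index)
    num = summary_condition.loc[common, "median"]
    den = summary_reference.loc[common, "median"]
    fold = num / den
    fold.name = "fold_change"
    return fold


def mean_log2_fold(folds: Sequence[float]) -> float:
    """Central fold across repeats: mean of log2 fold-changes (in log2 units).

    The mean is taken on the log2 scale (not log2 of the mean), so
    standard deviations can be computed directly on that scale.
    """
    folds = np.asarray(folds, dtype=float)
    if np.any(folds <= 0):
        raise ValueError("fold-changes must be positive")
    return float(np.mean(np.log2(folds)))


def robustness(folds):
    """Robustness score in percent: 100 * (1 - |1 - fold|).

    100 means the perturbation left the output unchanged; the score may
    be negative for folds above 2 (deviation beyond 100%).  NaN folds
    propagate.
    """
    if isinstance(folds, pd.Series):
        score = 100.0 * (1.0 - (1.0 - folds).abs())
        return score.rename("robustness")
    arr = np.asarray(folds, dtype=float)
    score = 100.0 * (1.0 - np.abs(1.0 - arr))
    return float(score) if score.ndim == 0 else score


def noise_iqr(values) -> float:
    """IQR of log10 of the positive values (linear-interpolation quantiles).

    The pipeline's cell-to-cell variance metric: gene-expression noise is
    approximately log-distributed, so Q3 - Q1 is taken on log10-scaled
    data after discarding non-positive values.  Undefined (NaN) with
    fewer than 4 positive values.
    """
    v = np.asarray(values, dtype=float)
    pos = v[np.isfinite(v) & (v > 0)]
    if pos.size < MIN_BIN_COUNT:
        return float("nan")
    logs = np.log10(pos)
    q1, q3 = np.quantile(logs, [0.25, 0.75])
    return float(q3 - q1)
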