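"""Agreement and activity statistics for behavior sequences.

The evaluation layer of automated behavioral coding: time budgets
(percent of observation time per behavior, out-of-view included),
cumulative activity curves, observer-referenced confusion matrices
(columns = manually observed truth, rows = model prediction), Kendall's
coefficient of concordance W with its chi-square p-value, and Spearman
rank correlations of nightly activity curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import OUT_OF_VIEW, EthogramConfig
from .io import BehaviorSequence

__all__ = [
    "TimeBudget",
    "ConfusionMatrix",
    "ConcordanceResult",
    "time_budget",
    "cumulative_curves",
    "confusion_matrix",
    "column_normalize",
    "kendalls_w",
    "concordance_pvalue",
    "spearman_rho",
    "pairwise_day_correlations",
]


@dataclass
class TimeBudget:
    """Percent of observation time per behavior (OUT_OF_VIEW included)."""

    percents: pd.Series  # index = label order, sums to 100
    total_duration_s: float

    @property
    def seconds(self) -> pd.Series:
        return self.percents * self.total_duration_s / 100.0


@dataclass
class ConfusionMatrix:
    """Predicted (rows) x observed (columns) seconds, fixed label order."""

    counts: pd.DataFrame

    @property
    def total(self) -> float:
        return float(self.counts.to_numpy().sum())

    def normalized(self) -> pd.DataFrame:
        return column_normalize(self)


@dataclass
class ConcordanceResult:
    """Kendall's W with the chi-square approximation of its p-value."""

    W: float
    m: int       # number of rankings (methods, nights, ...)
    n: int       # number of ranked items (behavior categories)
    chi2: float  # m * (n - 1) * W
    p: float     # upper tail of chi2_{n-1}
    tie_corrected: bool


def _labels_for(seq: BehaviorSequence, config: EthogramConfig | None) -> list[str]:
    if config is not None:
        return config.label_order
    seen = sorted({l for l in seq.labels if l != OUT_OF_VIEW})
    return seen + [OUT_OF_VIEW]


def time_budget(seq: BehaviorSequence,
                config: EthogramConfig | None = None) -> TimeBudget:
    """Percent of observation time per behavior.

    Seconds (or frames) labeled with each behavior are summed and
    transformed into percentages of the total observation time;
    OUT_OF_VIEW makes up the time where no behavior was observed or
    classified.
    """
    if seq.n_ticks == 0:
        raise ValueError("cannot compute a time budget of an empty sequence")
    order = _labels_for(seq, config)
    counts = pd.Series(0.0, index=order)
    vals, cnt = np.unique(seq.labels.astype(str), return_counts=True)
    for v, c in zip(vals, cnt):
        if v not in counts.index:
            raise ValueError(f"label {v!r} not in config label set")
        counts[v] = c
    percents = 100.0 * counts / counts.sum()
    return TimeBudget(percents=percents, total_duration_s=seq.duration_s)


def cumulative_curves(seq: BehaviorSequence,
                      config: EthogramConfig | None = None) -> pd.DataFrame:
    """Cumulative seconds spent per behavior, one column per label.

    Row ``t`` holds the total time spent in each behavior during ticks
    ``0..t``; every column is nondecreasing and the final row sums to
    the total duration.
    """
    if seq.resolution != "second":
        raise ValueError("cumulative_curves expects a second-resolution sequence")
    order = _labels_for(seq, config)
    n = seq.n_ticks
    onehot = np.zeros((n, len(order)))
    col_of = {name: i for i, name in enumerate(order)}
    for t, label in enumerate(seq.labels):
        if label not in col_of:
            raise ValueError(f"label {label!r} not in config label set")
        onehot[t, col_of[label]] = 1.0
    return pd.DataFrame(np.cumsum(onehot, axis=0), columns=order)


def confusion_matrix(pred: BehaviorSequence, obs: BehaviorSequence,
                     config: EthogramConfig | None = None) -> ConfusionMatrix:
    """Observer-referenced confusion matrix.

    ``counts[i, j]`` is the number of ticks where the model predicted
    behavior ``i`` while behavior ``j`` was manually observed: columns
    represent the observed behavior, rows the predicted one.
    """
    if pred.n_ticks != obs.n_ticks or pred.resolution != obs.resolution:
        raise ValueError(
            f"sequences differ in length/resolution: "
            f"{pred.n_ticks}@{pred.resolution} vs {obs.n_ticks}@{obs.resolution}"
        )
    if config is not None:
        order = config.label_order
        extra = ({l for l in obs.labels} | {l for l in pred.labels}) - set(order)
        if extra:
            raise ValueError(f"labels outside config label set: {sorted(extra)}")
    else:
        seen = sorted(
            ({l for l in obs.labels} | {l for l in pred.labels}) - {OUT_OF_VIEW}
        )
        order = seen + [OUT_OF_VIEW]
    k = len(order)
    code = {name: i for i, name in enumerate(order)}
    pi = np.fromiter((code[l] for l in pred.labels), dtype=np.int64,
                     count=pred.n_ticks)
    oi = np.fromiter((code[l] for l in obs.labels), dtype=np.int64,
                     count=obs.n_ticks)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (pi, oi), 1)
    return ConfusionMatrix(pd.DataFrame(counts, index=order, columns=order))


def column_normalize(cm: ConfusionMatrix) -> pd.DataFrame:
    """Normalize each observed-behavior column to sum to 1 (0 if empty)."""
    counts = cm.counts.astype(float)
    sums = counts.sum(axis=0)
    out = counts.copy()
    nonzero = sums > 0
    out.loc[:, nonzero] = counts.loc[:, nonzero] / sums[nonzero]
    out.loc[:, ~nonzero] = 0.0
    return out


def kendalls_w(table: np.ndarray | pd.DataFrame) -> ConcordanceResult:
    """Kendall's coefficient of concordance over an m x n value table.

    Each of the m rows (raters: methods, nights, ...) ranks the same n
    items (e.g. per-behavior time-budget sums); ties receive average
    ranks with the standard tie correction

        W = 12 * sum_i (R_i - m(n+1)/2)^2 / (m^2 (n^3 - n) - m * sum T),

    where R_i are item rank sums and T = sum (t^3 - t) over tie groups
    within each rater.  The p-value uses the large-sample chi-square
    approximation chi2 = m (n - 1) W on n - 1 degrees of freedom; this
    approximation is coarse for small m (see package docs).
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("rankings table must be 2-D (raters x items)")
    m, n = X.shape
    if m < 2 or n < 2:
        raise ValueError(f"need at least 2 raters and 2 items, got {m}x{n}")
    ranks = np.vstack([stats.rankdata(row) for row in X])
    R = ranks.sum(axis=0)
    S = float(((R - m * (n + 1) / 2.0) ** 2).sum())
    T = 0.0
    for row in ranks:
        _, tie_counts = np.unique(row, return_counts=True)
        T += float((tie_counts**3 - tie_counts).sum())
    denom = m**2 * (n**3 - n) - m * T
    if denom <= 0:
        raise ValueError("degenerate table: all items tied within every rater")
    W = 12.0 * S / denom
    W = float(min(max(W, 0.0), 1.0))
    chi2 = m * (n - 1) * W
    p = float(stats.chi2.sf(chi2, n - 1))
    return ConcordanceResult(W=W, m=m, n=n, chi2=chi2, p=p, tie_corrected=T > 0)


def concordance_pvalue(W: float, m: int, n: int) -> float:
    """Chi-square-approximation p-value for a given Kendall's W.

    ``chi2 = m * (n - 1) * W`` on ``n - 1`` degrees of freedom — the
    same approximation :func:`kendalls_w` applies to a value table.
    Useful for checking published W/p pairs where only W is given.
    """
    if not 0.0 <= W <= 1.0:
        raise ValueError(f"W must be in [0, 1], got {W}")
    if m < 2 or n < 2:
        raise ValueError(f"need m >= 2 and n >= 2, got m={m}, n={n}")
    return float(stats.chi2.sf(m * (n - 1) * W, n - 1))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises ``ValueError`` on constant input, where the coefficient is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def pairwise_day_correlations(
    curves: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Spearman correlation table across days (or subjects).

    ``curves`` maps a day key to an aligned activity series (typically
    the per-minute cumulative 'Lying down' curve of that night).
    Returns a symmetric table with unit diagonal.
    """
    keys = list(curves)
    if len(keys) < 2:
        raise ValueError("need at least 2 days")
    arrays = {k: np.asarray(v, dtype=float) for k, v in curves.items()}
    lengths = {k: a.shape[0] for k, a in arrays.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"misaligned series lengths: {lengths}")
    out = pd.DataFrame(np.eye(len(keys)), index=keys, columns=keys)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            rho = spearman_rho(arrays[a], arrays[b])
            out.loc[a, b] = rho
            out.loc[b, a] = rho
    return out
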