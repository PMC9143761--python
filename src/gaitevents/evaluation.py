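"""From likelihood traces to discrete events, and their scoring.

Predicted events are local maxima of a likelihood trace above a
threshold, thinned greedily (tallest first) under a minimum-separation
constraint.  Predicted and reference events are paired one-to-one by an
order-preserving dynamic program that first maximizes the number of
pairs within the matching tolerance and then minimizes the summed
absolute time error.  Paired events are true positives; unpaired
reference events are misses (FN) and unpaired predictions false alarms
(FP).  Detection quality is summarized as recall, precision and F1,
and timing quality as the median and inter-quartile range of the
per-pair time errors t_ref - t_pred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PeakConfig", "MatchResult", "DetectionMetrics", "UndefinedMetricError",
    "pick_peaks", "match_events", "detection_metrics", "time_error_stats",
    "round_half_up_percent",
]


class UndefinedMetricError(ZeroDivisionError):
    """Recall or precision has a zero denominator."""


@dataclass(frozen=True)
class PeakConfig:
    """Rule for turning a likelihood trace into discrete event times."""

    threshold: float = 0.3
    min_separation_s: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        if self.min_separation_s <= 0:
            raise ValueError("min_separation_s must be positive")


@dataclass
class MatchResult:
    """One-to-one pairing of reference and predicted events of one trial."""

    pairs: list[tuple[float, float]]
    fn: int
    fp: int
    time_errors: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.time_errors is None:
            self.time_errors = np.array([r - p for r, p in self.pairs])

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def n_ref(self) -> int:
        return self.tp + self.fn

    @property
    def n_pred(self) -> int:
        return self.tp + self.fp

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(pairs=self.pairs + other.pairs,
                           fn=self.fn + other.fn, fp=self.fp + other.fp)


def pick_peaks(trace: np.ndarray, fs: float,
               cfg: PeakConfig | None = None) -> np.ndarray:
    """Event times (s) from a likelihood trace.

    Local maxima above ``cfg.threshold`` are kept greedily in descending
    height while enforcing ``cfg.min_separation_s`` between survivors.
    """
    cfg = cfg or PeakConfig()
    trace = np.asarray(trace, dtype=float)
    idx, _ = find_peaks(trace, height=cfg.threshold,
                        distance=max(1, int(round(cfg.min_separation_s * fs))))
    return idx / fs


def match_events(ref: np.ndarray, pred: np.ndarray,
                 tolerance_s: float) -> MatchResult:
    """Optimal order-preserving one-to-one pairing within a tolerance.

    Among all pairings whose every pair satisfies ``|t_ref - t_pred| <=
    tolerance_s``, the dynamic program maximizes the number of pairs and,
    among those, minimizes the total absolute time error.  Per-pair time
    errors follow the convention ``t_ref - t_pred`` (positive when the
    prediction is early).
    """
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    for name, t in (("ref", ref), ("pred", pred)):
        if np.any(np.diff(t) < 0):
            raise ValueError(f"{name} event times must be sorted ascending")
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be non-negative")

    nr, npd = len(ref), len(pred)
    # dp[i][j]: best (-pairs, cost) for ref[:i] vs pred[:j]
    dp = [[(0, 0.0)] * (npd + 1) for _ in range(nr + 1)]
    for i in range(1, nr + 1):
        for j in range(1, npd + 1):
            best = min(dp[i - 1][j], dp[i][j - 1])
            delta = abs(ref[i - 1] - pred[j - 1])
            if delta <= tolerance_s:
                prev = dp[i - 1][j - 1]
                cand = (prev[0] - 1, prev[1] + delta)
                best = min(best, cand)
            dp[i][j] = best
    # backtrack (recompute candidates exactly as in the forward pass so
    # float comparisons are bitwise-safe)
    pairs = []
    i, j = nr, npd
    while i > 0 and j > 0:
        here = dp[i][j]
        delta = abs(ref[i - 1] - pred[j - 1])
        prev = dp[i - 1][j - 1]
        if delta <= tolerance_s and here == (prev[0] - 1, prev[1] + delta):
            pairs.append((float(ref[i - 1]), float(pred[j - 1])))
            i, j = i - 1, j - 1
        elif dp[i - 1][j] == here:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return MatchResult(pairs=pairs, fn=nr - len(pairs), fp=npd - len(pairs))


@dataclass(frozen=True)
class DetectionMetrics:
    recall: float
    precision: float
    f1: float

    @property
    def recall_pct(self) -> int:
        return round_half_up_percent(self.recall)

    @property
    def precision_pct(self) -> int:
        return round_half_up_percent(self.precision)

    @property
    def f1_pct(self) -> int:
        return round_half_up_percent(self.f1)


def round_half_up_percent(fraction: float) -> int:
    """Integer percent with exact half-up rounding (0.915 -> 92)."""
    return int(math.floor(fraction * 100 + 0.5))


def detection_metrics(m: MatchResult | tuple[int, int, int]) -> DetectionMetrics:
    """recall = TP/(TP+FN), precision = TP/(TP+FP), F1 their harmonic mean."""
    tp, fn, fp = (m.tp, m.fn, m.fp) if isinstance(m, MatchResult) else m
    if tp + fn == 0 or tp + fp == 0:
        raise UndefinedMetricError("recall/precision undefined: no reference "
                                   "or no predicted events")
    recall = tp / (tp + fn)
    precision = tp / (tp + fp)
    f1 = 0.0 if tp == 0 else 2 * recall * precision / (recall + precision)
    return DetectionMetrics(recall=recall, precision=precision, f1=f1)


def time_error_stats(errors) -> tuple[float, float]:
    """Median and inter-quartile range (linear-interpolation quantiles)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("no time errors to summarize")
    q1, med, q3 = np.percentile(errors, [25, 50, 75])
    return float(med), float(q3 - q1)
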