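"""Stride-specific temporal parameters and Bland-Altman agreement.

From a foot's alternating IC/FC sequence, every consecutive triplet
IC_i, FC_i, IC_{i+1} yields one stride:

* stride time = IC_{i+1} - IC_i
* stance time = FC_i - IC_i
* swing  time = IC_{i+1} - FC_i

so stance + swing = stride by construction.  Agreement between
reference-derived and model-derived parameters is quantified per
Bland-Altman: mean difference and 95% limits of agreement
mean +/- 1.96 x SD of the paired differences.  Only trials in which
every event was detected and no false positives occurred contribute
strides to the agreement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import FootEvents, SequencingError
from .evaluation import MatchResult

__all__ = ["StrideParams", "AgreementStats", "compute_stride_params",
           "trial_is_valid", "bland_altman"]


@dataclass(frozen=True)
class StrideParams:
    """Temporal parameters of one stride of one foot."""

    ic_time_s: float
    stride_time_s: float
    stance_time_s: float
    swing_time_s: float


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of paired reference-vs-predicted values."""

    mean_difference_s: float
    loa_low_s: float
    loa_high_s: float
    n: int


def compute_stride_params(events: FootEvents) -> list[StrideParams]:
    """Stride/stance/swing times from one foot's event sequence.

    Requires the interleaved sequence to alternate IC/FC; incomplete
    trailing patterns (an IC without a following FC and IC) are dropped.
    A single IC yields no strides.
    """
    events.check_alternation()
    ics, fcs = events.ic_times, events.fc_times
    out = []
    for i in range(len(ics) - 1):
        ic, ic_next = ics[i], ics[i + 1]
        between = fcs[(fcs > ic) & (fcs < ic_next)]
        if len(between) != 1:       # unreachable after alternation check
            raise SequencingError("expected exactly one FC between two ICs")
        fc = float(between[0])
        out.append(StrideParams(ic_time_s=float(ic),
                                stride_time_s=float(ic_next - ic),
                                stance_time_s=float(fc - ic),
                                swing_time_s=float(ic_next - fc)))
    return out


def trial_is_valid(match_ic: MatchResult, match_fc: MatchResult) -> bool:
    """True iff every event was detected and nothing spurious: FN = FP = 0."""
    return (match_ic.fn == 0 and match_ic.fp == 0
            and match_fc.fn == 0 and match_fc.fp == 0)


def bland_altman(ref_vals, pred_vals) -> tuple[AgreementStats, np.ndarray, np.ndarray]:
    """Mean difference and 95% limits of agreement of paired values.

    Differences are ``d_i = ref_i - pred_i``; the limits are
    ``mean(d) +/- 1.96 * SD(d)`` with the sample (n-1) standard
    deviation.  Also returns the per-pair (mean, difference) coordinates
    for the conventional scatter plot.
    """
    ref = np.asarray(ref_vals, dtype=float)
    pred = np.asarray(pred_vals, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("ref and pred must be equally long 1-D sequences")
    if len(ref) < 2:
        raise ValueError("need at least two paired values")
    d = ref - pred
    mean_d = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    stats = AgreementStats(mean_difference_s=mean_d,
                           loa_low_s=mean_d - 1.96 * sd,
                           loa_high_s=mean_d + 1.96 * sd,
                           n=len(d))
    return stats, (ref + pred) / 2.0, d
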