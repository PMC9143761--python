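"""Published benchmark confusion counts for this detection approach.

A validation study of TCN-based gait-event detection on 157 healthy and
neurological participants (young and older adults, Parkinson's disease,
multiple sclerosis, stroke, chronic low back pain, other) reported, per
sensor location and event type, the true-positive, false-negative and
false-positive counts of the model against marker-based reference
annotations on its held-out test set.  The counts are inputs from which
recall, precision and F1 are recomputed at run time; they also anchor
the summary bounds (minimum recall 92%, minimum precision 97% across
the eight location x event combinations) quoted for the approach.
"""

from __future__ import annotations

from .evaluation import DetectionMetrics, detection_metrics

__all__ = ["BENCHMARK_COUNTS", "BENCHMARK_FS_HZ", "benchmark_metrics"]

#: Sampling frequency of the benchmark recordings (Hz); one sample period
#: is therefore 1/200 = 0.005 s.
BENCHMARK_FS_HZ = 200.0

#: (location, event) -> (TP, FN, FP) on the benchmark test set.
BENCHMARK_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("left_ankle", "IC"): (624, 19, 5),
    ("left_ankle", "FC"): (606, 32, 10),
    ("right_ankle", "IC"): (599, 42, 8),
    ("right_ankle", "FC"): (614, 17, 12),
    ("left_shank", "IC"): (605, 38, 15),
    ("left_shank", "FC"): (585, 53, 18),
    ("right_shank", "IC"): (603, 36, 15),
    ("right_shank", "FC"): (595, 30, 9),
}


def benchmark_metrics() -> dict[tuple[str, str], DetectionMetrics]:
    """Recall/precision/F1 recomputed from the benchmark counts."""
    return {key: detection_metrics(counts)
            for key, counts in BENCHMARK_COUNTS.items()}
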