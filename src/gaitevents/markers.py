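"""Marker-based reference annotation of gait events.

Heel and toe trajectories from an optoelectronic capture system are
gap-filled, low-pass filtered with a zero-phase Butterworth filter
(6th order, 20 Hz cut-off by default), differentiated to vertical
velocity, and annotated: initial contacts at local minima of the heel
vertical velocity, final contacts at local maxima of the toe vertical
velocity.  The resulting events serve as the reference ("true") timings
against which IMU-based detections are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from .events import FootEvents, GaitEvents
from .synthetic import MarkerTrial

__all__ = [
    "FilterSpec", "BoundaryGapError", "UnfillableGapError",
    "fill_marker_gaps", "lowpass_zero_phase", "differentiate",
    "detect_reference_events",
]


class BoundaryGapError(ValueError):
    """A marker gap touches the first or last sample of the trial."""


class UnfillableGapError(ValueError):
    """Too many missing samples, or a gap longer than the allowed maximum."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass design for marker smoothing."""

    order: int = 6
    cutoff_hz: float = 20.0
    fs: float = 200.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be even and >= 2")
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ValueError("cutoff_hz must lie in (0, Nyquist)")


def fill_marker_gaps(trajectory: np.ndarray, fs: float = 200.0,
                     max_gap_s: float = 0.5,
                     max_missing_fraction: float = 0.2) -> np.ndarray:
    """Fill NaN-flagged gaps in an N x 3 trajectory by cubic-spline interpolation.

    Each coordinate is splined over its observed samples and evaluated at
    the gap samples; observed samples are returned untouched.  Gaps that
    touch either end of the trial cannot be interpolated and raise
    :class:`BoundaryGapError`; trajectories with more than
    ``max_missing_fraction`` missing or any gap longer than ``max_gap_s``
    raise :class:`UnfillableGapError`.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 3:
        raise ValueError("trajectory must be N x 3")
    missing = np.any(np.isnan(traj), axis=1)
    if not missing.any():
        return traj.copy()
    if missing.mean() > max_missing_fraction:
        raise UnfillableGapError(
            f"{missing.mean():.0%} of samples missing "
            f"(limit {max_missing_fraction:.0%})")
    if missing[0] or missing[-1]:
        raise BoundaryGapError("gap touches the trial boundary")

    # per-gap length check
    edges = np.flatnonzero(np.diff(missing.astype(int)))
    starts, stops = edges[::2] + 1, edges[1::2] + 1
    max_len = int(round(max_gap_s * fs))
    for a, b in zip(starts, stops):
        if b - a > max_len:
            raise UnfillableGapError(
                f"gap of {(b - a) / fs:.3f} s exceeds maximum {max_gap_s} s")

    out = traj.copy()
    idx = np.arange(len(traj))
    for c in range(3):
        spline = CubicSpline(idx[~missing], traj[~missing, c])
        out[missing, c] = spline(idx[missing])
    return out


def lowpass_zero_phase(x: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth low-pass: forward pass, reverse, second pass.

    The forward-backward application squares the magnitude response
    (an order-``spec.order`` design acts with effective order 2x) and
    cancels the phase lag, so events keep their timing.  Unit DC gain
    and the input length are preserved.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if len(x) <= 3 * spec.order:
        raise ValueError("signal too short for stable filtering")
    b, a = butter(spec.order, spec.cutoff_hz, fs=spec.fs)
    if not spec.zero_phase:
        from scipy.signal import lfilter, lfilter_zi
        zi = lfilter_zi(b, a) * x[0]
        y, _ = lfilter(b, a, x, zi=zi)
        return y
    return filtfilt(b, a, x)


def differentiate(position: np.ndarray, fs: float) -> np.ndarray:
    """Velocity by central differences (one-sided at the ends), units per second."""
    position = np.asarray(position, dtype=float)
    if position.ndim != 1 or len(position) < 3:
        raise ValueError("position must be 1-D with at least 3 samples")
    return np.gradient(position) * fs


def _extrema(v: np.ndarray, fs: float, minima: bool,
             min_separation_s: float, prominence_frac: float) -> np.ndarray:
    span = float(np.ptp(v))
    if span < 1e-12:            # flat signal (e.g., quiet standing): no events
        return np.array([], dtype=int)
    sig = -v if minima else v
    peaks, _ = find_peaks(sig, distance=max(1, int(round(min_separation_s * fs))),
                          prominence=prominence_frac * span)
    return peaks


def detect_reference_events(markers: MarkerTrial,
                            spec: FilterSpec | None = None,
                            min_separation_s: float = 0.3,
                            prominence_frac: float = 0.1,
                            ic_source: str = "heel", fc_source: str = "toe",
                            ) -> GaitEvents:
    """Annotate IC and FC per foot from vertical marker velocities.

    Per foot: the configured marker's vertical position is filtered and
    differentiated; ICs are taken at local minima of the heel velocity
    (the heel decelerates downward into ground contact) and FCs at local
    maxima of the toe velocity (the toe accelerates upward at toe-off).
    Peaks must be separated by ``min_separation_s`` and exceed a
    prominence of ``prominence_frac`` of the velocity range; a trial with
    no qualifying extremum simply yields no events.
    """
    spec = spec or FilterSpec(fs=markers.fs)
    vax = markers.vertical_axis
    feet = {}
    for foot, mf in markers.feet.items():
        traj = {"heel": mf.heel, "toe": mf.toe}
        v = {}
        for name, m in traj.items():
            z = lowpass_zero_phase(m[:, vax], spec)
            v[name] = differentiate(z, markers.fs)
        ic_idx = _extrema(v[ic_source], markers.fs, minima=True,
                          min_separation_s=min_separation_s,
                          prominence_frac=prominence_frac)
        fc_idx = _extrema(v[fc_source], markers.fs, minima=False,
                          min_separation_s=min_separation_s,
                          prominence_frac=prominence_frac)
        feet[foot] = FootEvents(ic_idx / markers.fs, fc_idx / markers.fs)
    return GaitEvents(feet=feet, fs=markers.fs)
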