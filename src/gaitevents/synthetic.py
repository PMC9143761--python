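"""Synthetic straight-line walking trials with ground-truth gait events.

Emulates short (~5 m) walking bouts recorded simultaneously by an
optoelectronic marker system (heel and toe markers of both feet) and four
lower-leg IMUs (left/right ankle, left/right shank) at a common 200 Hz
clock, for cohorts of healthy and neurologically impaired walkers at
slow / preferred / fast speed.

The waveform model keeps every ground-truth event in closed form:

* Marker vertical *velocities* are sums of well-separated Gaussian bumps.
  The heel's downward-velocity peak is placed exactly at each initial
  contact (IC) and the toe's upward-velocity peak exactly at each final
  contact (FC), so the velocity-extremum annotation convention recovers
  the generating schedule to the sample.  Positions are the analytic
  integrals (Gaussian CDFs), hence smooth, periodic heel-lift/toe-lift
  curves that never go below ground.
* The shank/ankle medio-lateral angular velocity follows the canonical
  lower-leg template: a dominant positive mid-swing peak flanked by
  negative deflections at IC and FC.  Accelerometer channels carry a
  gravity component, a sharp impact transient at IC and smoother
  braking/propulsion lobes, so IC and FC remain identifiable from
  rotation-invariant signal structure.

Each sensor is mounted in an arbitrary orientation: a random 3-D rotation
is applied jointly to all accelerometer and gyroscope samples of a
stream.  Additive white Gaussian sensor noise is scaled per channel
relative to that channel's signal standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.special import erf

from .events import FootEvents, GaitEvents

__all__ = [
    "SubjectSpec", "ImuTrial", "MarkerFoot", "MarkerTrial", "SyntheticTrial",
    "GROUP_PROFILES", "DEFAULT_GROUP_SIZES", "SPEED_FACTORS", "LOCATIONS",
    "generate_cohort", "simulate_trial", "apply_random_rotation",
    "rotate_imu", "add_sensor_noise", "write_trial", "read_trial",
]

LOCATIONS = ("left_ankle", "right_ankle", "left_shank", "right_shank")
SPEED_FACTORS = {"slow": 0.7, "preferred": 1.0, "fast": 1.3}

#: Cohort composition used as default sampling weights: group -> {gender: count}
#: (157 participants across healthy and neurological groups).
DEFAULT_GROUP_SIZES = {
    "YA":     {"F": 21, "M": 21},
    "OA":     {"F": 12, "M": 10},
    "PD":     {"F": 12, "M": 19},
    "MS":     {"F": 12, "M": 9},
    "stroke": {"F": 4,  "M": 17},
    "cLBP":   {"F": 3,  "M": 6},
    "other":  {"F": 3,  "M": 8},
}

#: Per-group gait-timing distributions: cadence (strides/s) mean/sd,
#: stance fraction mean/sd, asymmetry low/high (uniform), IMU noise SD
#: (relative to per-channel signal SD).  Pathological groups walk with
#: slower cadence and larger left-right asymmetry than young adults.
GROUP_PROFILES = {
    "YA":     dict(cad=(1.00, 0.07), stance=(0.60, 0.015), asym=(0.00, 0.02), noise_sd=0.05),
    "OA":     dict(cad=(0.92, 0.07), stance=(0.61, 0.015), asym=(0.00, 0.03), noise_sd=0.05),
    "PD":     dict(cad=(0.85, 0.08), stance=(0.63, 0.020), asym=(0.01, 0.06), noise_sd=0.06),
    "MS":     dict(cad=(0.85, 0.08), stance=(0.62, 0.020), asym=(0.01, 0.06), noise_sd=0.06),
    "stroke": dict(cad=(0.80, 0.08), stance=(0.63, 0.025), asym=(0.02, 0.10), noise_sd=0.06),
    "cLBP":   dict(cad=(0.92, 0.07), stance=(0.61, 0.015), asym=(0.00, 0.04), noise_sd=0.05),
    "other":  dict(cad=(0.90, 0.08), stance=(0.62, 0.020), asym=(0.00, 0.05), noise_sd=0.06),
}

GROUPS = tuple(GROUP_PROFILES)


@dataclass(frozen=True)
class SubjectSpec:
    """Gait-timing parameters of one synthetic walker."""

    subject_id: str
    group: str
    gender: str
    cadence_hz: float          # strides per second at preferred speed
    stance_fraction: float     # fraction of the stride spent in stance
    asymmetry: float           # left-right timing offset fraction of a stride
    noise_sd: float            # sensor noise SD relative to channel signal SD

    def __post_init__(self) -> None:
        if self.cadence_hz <= 0:
            raise ValueError("cadence_hz must be positive")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if not 0.0 <= self.asymmetry <= 0.2:
            raise ValueError("asymmetry must lie in [0, 0.2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ImuTrial:
    """One sensor stream: N x 6 array [acc x,y,z (m/s^2), gyr x,y,z (deg/s)]."""

    X: np.ndarray
    fs: float = 200.0
    location: str = "left_shank"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 6:
            raise ValueError("IMU array must be N x 6")
        if self.X.shape[0] < 1:
            raise ValueError("IMU array must contain at least one sample")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("IMU array contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def acc(self) -> np.ndarray:
        return self.X[:, :3]

    @property
    def gyr(self) -> np.ndarray:
        return self.X[:, 3:]


@dataclass
class MarkerFoot:
    """Heel and toe marker trajectories (N x 3, meters) of one foot."""

    heel: np.ndarray
    toe: np.ndarray


@dataclass
class MarkerTrial:
    """Marker trajectories of both feet; vertical axis is the third coordinate."""

    feet: dict[str, MarkerFoot]
    fs: float = 200.0
    vertical_axis: int = 2

    def __getitem__(self, foot: str) -> MarkerFoot:
        return self.feet[foot]


@dataclass
class SyntheticTrial:
    imu: dict[str, ImuTrial]
    markers: MarkerTrial
    truth: GaitEvents
    speed_condition: str
    fs: float
    subject: SubjectSpec | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(n_subjects: int,
                    group_weights: dict[str, float] | None = None,
                    seed: int = 0) -> list[SubjectSpec]:
    """Draw ``n_subjects`` subject specifications.

    ``group_weights`` maps group name to a non-negative sampling weight
    (default: proportional to the reference cohort composition).  The
    draw is fully reproducible given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if group_weights is None:
        group_weights = {g: sum(c.values()) for g, c in DEFAULT_GROUP_SIZES.items()}
    for g in group_weights:
        if g not in GROUP_PROFILES:
            raise ValueError(f"unknown group {g!r}")
    w = np.array([group_weights.get(g, 0.0) for g in GROUPS], dtype=float)
    if np.any(w < 0):
        raise ValueError("group weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("group weights must sum to a positive value")
    w = w / w.sum()

    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        group = GROUPS[rng.choice(len(GROUPS), p=w)]
        sizes = DEFAULT_GROUP_SIZES[group]
        p_female = sizes["F"] / (sizes["F"] + sizes["M"])
        gender = "F" if rng.random() < p_female else "M"
        prof = GROUP_PROFILES[group]
        cadence = float(np.clip(rng.normal(*prof["cad"]), 0.4, 1.6))
        stance = float(np.clip(rng.normal(*prof["stance"]), 0.45, 0.75))
        asym = float(rng.uniform(*prof["asym"]))
        cohort.append(SubjectSpec(
            subject_id=f"S{i + 1:03d}", group=group, gender=gender,
            cadence_hz=cadence, stance_fraction=stance, asymmetry=asym,
            noise_sd=prof["noise_sd"],
        ))
    return cohort


# ---------------------------------------------------------------------------
# waveform primitives


def _gauss(t: np.ndarray, center: float, width_s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width_s) ** 2)


def _step(t: np.ndarray, center: float, width_s: float) -> np.ndarray:
    """Gaussian CDF smooth step 0 -> 1 with maximum slope exactly at ``center``."""
    return 0.5 * (1.0 + erf((t - center) / (np.sqrt(2.0) * width_s)))


def _snap(times: np.ndarray, fs: float) -> np.ndarray:
    return np.rint(np.asarray(times) * fs) / fs


def _event_schedule(subject: SubjectSpec, stride_s: float, n_strides: int,
                    fs: float) -> dict[str, FootEvents]:
    """Closed-form IC/FC schedule per foot, snapped to the sample grid.

    Each foot performs ``n_strides`` ICs with an FC between every
    consecutive pair (n ICs, n-1 FCs: the merged sequence alternates
    IC, FC, ..., IC).  The right foot is offset by half a stride plus
    the subject's asymmetry fraction.
    """
    t0_left = 0.6 * stride_s
    offsets = {"left": t0_left,
               "right": t0_left + stride_s * (0.5 + subject.asymmetry)}
    feet = {}
    for foot, t0 in offsets.items():
        ics = t0 + stride_s * np.arange(n_strides)
        fcs = ics[:-1] + subject.stance_fraction * stride_s
        feet[foot] = FootEvents(_snap(ics, fs), _snap(fcs, fs))
    return feet


def _marker_foot(t: np.ndarray, fe: FootEvents, stride_s: float,
                 stance: float, side: str, cadence: float) -> MarkerFoot:
    ics, fcs = fe.ic_times, fe.fc_times
    w = 0.05                    # marker bump width (s)
    heel_amp, toe_amp = 0.08, 0.04

    # heel: lifts during late stance, comes down with peak downward
    # velocity exactly at each IC; one lead-in lift precedes the first IC
    rises = np.concatenate([[ics[0] - 0.35 * stride_s],
                            ics[:-1] + 0.7 * stance * stride_s])
    heel_z = 0.01 + heel_amp * (
        sum(_step(t, r, w) for r in rises) - sum(_step(t, c, w) for c in ics))

    # toe: leaves the ground with peak upward velocity exactly at each FC,
    # lands shortly after the following IC
    lands = ics[1:] + 0.05 * stride_s
    toe_z = 0.01 + toe_amp * (
        sum(_step(t, c, w) for c in fcs) - sum(_step(t, c, w) for c in lands))

    speed_mps = 1.1 * cadence
    lateral = 0.08 if side == "left" else -0.08
    heel = np.column_stack([speed_mps * t, np.full_like(t, lateral), heel_z])
    toe = np.column_stack([speed_mps * t + 0.22, np.full_like(t, lateral), toe_z])
    return MarkerFoot(heel=heel, toe=toe)


def _imu_local(t: np.ndarray, fe: FootEvents, stride_s: float,
               location: str) -> np.ndarray:
    """Canonical (unrotated) 6-channel IMU template for one foot's schedule."""
    ics, fcs = fe.ic_times, fe.fc_times
    ankle = location.endswith("ankle")
    a_sw = 320.0 if ankle else 250.0      # mid-swing peak, deg/s
    a_ic, a_fc = 120.0, 140.0
    w_sw = 0.10 * stride_s

    gyr_ml = np.zeros_like(t)
    mids = 0.5 * (fcs + ics[1:])          # mid-swing instants
    pre_mid = ics[0] - 0.20 * stride_s    # lead-in step before the first IC
    for m in np.concatenate([[pre_mid], mids]):
        gyr_ml += a_sw * _gauss(t, m, w_sw)
    for c in ics:
        gyr_ml -= a_ic * _gauss(t, c, 0.03)
    for c in fcs:
        gyr_ml -= a_fc * _gauss(t, c, 0.05)

    phase = 2 * np.pi * t / stride_s
    gyr_x = 20.0 * np.sin(phase)
    gyr_z = 10.0 * np.sin(phase + 1.0)

    acc_v = np.full_like(t, 9.81) + 1.5 * np.sin(phase + 0.5)
    acc_ap = 1.0 * np.sin(phase)
    for c in ics:                         # sharp, narrow impact transient
        acc_v += 25.0 * _gauss(t, c, 0.02)
        acc_ap -= 4.0 * _gauss(t, c, 0.04)
    for c in fcs:                         # wider propulsion lobe
        acc_ap += 3.0 * _gauss(t, c, 0.06)
    acc_lat = 0.5 * np.sin(2 * phase)

    return np.column_stack([acc_ap, acc_lat, acc_v, gyr_x, gyr_ml, gyr_z])


def simulate_trial(subject: SubjectSpec, speed: str = "preferred",
                   fs: float = 200.0, seed: int = 0, n_strides: int = 8,
                   rotate: bool = True) -> SyntheticTrial:
    """Simulate one walking trial of ``subject`` at a speed condition.

    Returns synchronized marker trajectories, four IMU streams and the
    ground-truth event schedule.  Identical arguments give bit-identical
    trials.  ``rotate`` draws an independent random mounting orientation
    per sensor; sensor noise follows ``subject.noise_sd`` and marker
    noise a small proportional fraction of it.
    """
    if speed not in SPEED_FACTORS:
        raise ValueError(f"speed must be one of {sorted(SPEED_FACTORS)}")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if n_strides < 2:
        raise ValueError("n_strides must be >= 2")

    cadence = subject.cadence_hz * SPEED_FACTORS[speed]
    stride_s = 1.0 / cadence
    feet = _event_schedule(subject, stride_s, n_strides, fs)

    last_event = max(fe.ic_times[-1] for fe in feet.values())
    n = int(round((last_event + 0.8 * stride_s) * fs)) + 1
    t = np.arange(n) / fs

    rng = np.random.default_rng(seed)
    marker_feet = {
        foot: _marker_foot(t, fe, stride_s, subject.stance_fraction, foot, cadence)
        for foot, fe in feet.items()
    }
    marker_noise = subject.noise_sd * 0.003   # meters; 0 when noise-free
    if marker_noise > 0:
        for mf in marker_feet.values():
            mf.heel = mf.heel + rng.normal(0.0, marker_noise, mf.heel.shape)
            mf.toe = mf.toe + rng.normal(0.0, marker_noise, mf.toe.shape)
            mf.heel[:, 2] = np.maximum(mf.heel[:, 2], 0.0)
            mf.toe[:, 2] = np.maximum(mf.toe[:, 2], 0.0)
    markers = MarkerTrial(feet=marker_feet, fs=fs)

    imu = {}
    for loc in LOCATIONS:
        foot = "left" if loc.startswith("left") else "right"
        stream = ImuTrial(_imu_local(t, feet[foot], stride_s, loc), fs=fs,
                          location=loc)
        if rotate:
            stream = rotate_imu(stream, Rotation.random(rng=rng).as_matrix())
        if subject.noise_sd > 0:
            sd = subject.noise_sd * stream.X.std(axis=0)
            stream = ImuTrial(stream.X + rng.normal(0.0, 1.0, stream.X.shape) * sd,
                              fs=fs, location=loc)
        imu[loc] = stream

    truth = GaitEvents(feet=feet, fs=fs)
    return SyntheticTrial(imu=imu, markers=markers, truth=truth,
                          speed_condition=speed, fs=fs, subject=subject,
                          meta={"seed": seed, "n_strides": n_strides})


# ---------------------------------------------------------------------------
# augmentation


def rotate_imu(imu: ImuTrial, R: np.ndarray) -> ImuTrial:
    """Apply one 3-D rotation matrix to every acc and gyr sample."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("R must be a 3x3 rotation matrix")
    X = np.hstack([imu.acc @ R.T, imu.gyr @ R.T])
    return ImuTrial(X, fs=imu.fs, location=imu.location)


def apply_random_rotation(imu: ImuTrial, seed: int = 0) -> ImuTrial:
    """Rotate the whole stream by a uniformly random 3-D rotation."""
    rng = np.random.default_rng(seed)
    return rotate_imu(imu, Rotation.random(rng=rng).as_matrix())


def add_sensor_noise(imu: ImuTrial, noise_sd, seed: int = 0) -> ImuTrial:
    """Add zero-mean white Gaussian noise, independent per sample and channel.

    ``noise_sd`` is a scalar or length-6 per-channel SD in the channel's
    physical units; 0 returns the input unchanged.
    """
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (6,))
    if np.any(sd < 0):
        raise ValueError("noise_sd must be non-negative")
    if np.all(sd == 0):
        return imu
    rng = np.random.default_rng(seed)
    return ImuTrial(imu.X + rng.normal(0.0, 1.0, imu.X.shape) * sd,
                    fs=imu.fs, location=imu.location)


# ---------------------------------------------------------------------------
# trial file round-trip

_IMU_COLS = ["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
_MARKER_COLS = ["heel_x", "heel_y", "heel_z", "toe_x", "toe_y", "toe_z"]


def write_trial(trial: SyntheticTrial, outdir: str | Path) -> Path:
    """Write one trial as flat CSV/JSON files; returns the trial directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = np.arange(next(iter(trial.imu.values())).n_samples) / trial.fs
    for loc, stream in trial.imu.items():
        df = pd.DataFrame(stream.X, columns=_IMU_COLS)
        df.insert(0, "time_s", t)
        df.to_csv(outdir / f"imu_{loc}.csv", index=False, float_format="%.9g")
    for foot, mf in trial.markers.feet.items():
        df = pd.DataFrame(np.hstack([mf.heel, mf.toe]), columns=_MARKER_COLS)
        df.insert(0, "time_s", t)
        df.to_csv(outdir / f"markers_{foot}.csv", index=False, float_format="%.9g")
    trial.truth.save_json(outdir / "events_truth.json")
    meta = {"fs": trial.fs, "speed_condition": trial.speed_condition,
            **trial.meta}
    if trial.subject is not None:
        meta["subject"] = vars(trial.subject)
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    return outdir


def read_trial(trial_dir: str | Path) -> SyntheticTrial:
    trial_dir = Path(trial_dir)
    meta = json.loads((trial_dir / "meta.json").read_text())
    fs = float(meta["fs"])
    imu = {}
    for path in sorted(trial_dir.glob("imu_*.csv")):
        loc = path.stem[len("imu_"):]
        df = pd.read_csv(path)
        imu[loc] = ImuTrial(df[_IMU_COLS].to_numpy(), fs=fs, location=loc)
    feet = {}
    for path in sorted(trial_dir.glob("markers_*.csv")):
        foot = path.stem[len("markers_"):]
        df = pd.read_csv(path)
        feet[foot] = MarkerFoot(heel=df[_MARKER_COLS[:3]].to_numpy(),
                                toe=df[_MARKER_COLS[3:]].to_numpy())
    truth = GaitEvents.load_json(trial_dir / "events_truth.json", fs=fs)
    subject = None
    if "subject" in meta:
        subject = SubjectSpec(**meta["subject"])
    return SyntheticTrial(imu=imu, markers=MarkerTrial(feet=feet, fs=fs),
                          truth=truth, speed_condition=meta["speed_condition"],
                          fs=fs, subject=subject,
                          meta={k: v for k, v in meta.items()
                                if k not in ("fs", "speed_condition", "subject")})
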