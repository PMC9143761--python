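"""From trials and events to model inputs and targets.

Sensor channels are standardized per trial (zero mean, unit SD per
channel); event lists become per-sample likelihood targets in [0, 1]
by placing a Gaussian bump of width ``sigma`` samples at every event
(max-combined where bumps overlap); training/validation streams are cut
into fixed-length windows (400 samples with 50% overlap by default),
while at test time complete trials are fed to the fully convolutional
model.  Subjects are split into train/validation/test sets at the
subject level, stratified by diagnostic group and gender.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import FootEvents
from .synthetic import SubjectSpec

__all__ = [
    "DegenerateChannelError", "LabelSeries", "WindowSet", "DatasetSplit",
    "normalize_channels", "encode_event_labels", "make_windows",
    "concat_window_sets", "split_cohort",
]


class DegenerateChannelError(ValueError):
    """A channel has zero variance and cannot be standardized."""


@dataclass
class LabelSeries:
    """Per-sample IC/FC likelihood targets in [0, 1]."""

    yic: np.ndarray
    yfc: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.yic = np.asarray(self.yic, dtype=float)
        self.yfc = np.asarray(self.yfc, dtype=float)
        if self.yic.shape != self.yfc.shape or self.yic.ndim != 1:
            raise ValueError("yic and yfc must be 1-D and equally long")

    @property
    def stacked(self) -> np.ndarray:
        """N x 2 array, columns (IC, FC)."""
        return np.column_stack([self.yic, self.yfc])


@dataclass
class WindowSet:
    """Fixed-length training windows with their targets and provenance."""

    windows: np.ndarray          # M x window x D
    targets: np.ndarray          # M x window x 2
    trial_ids: np.ndarray        # M strings
    start_samples: np.ndarray    # M ints
    window: int = 400
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.targets):
            raise ValueError("windows and targets must align")

    def __len__(self) -> int:
        return len(self.windows)

    def save(self, path: str | Path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("windows", data=self.windows)
            f.create_dataset("targets", data=self.targets)
            f.create_dataset("trial_ids", data=np.asarray(self.trial_ids, dtype="S"))
            f.create_dataset("start_samples", data=self.start_samples)
            f.attrs["window"] = self.window
            f.attrs["overlap"] = self.overlap

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(windows=f["windows"][()], targets=f["targets"][()],
                       trial_ids=f["trial_ids"][()].astype(str),
                       start_samples=f["start_samples"][()],
                       window=int(f.attrs["window"]),
                       overlap=float(f.attrs["overlap"]))


@dataclass
class DatasetSplit:
    """Disjoint subject-id lists for train / validation / test."""

    train: list[str]
    validation: list[str]
    test: list[str]
    strata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split sets must be disjoint")

    def set_of(self, subject_id: str) -> str:
        for name in ("train", "validation", "test"):
            if subject_id in getattr(self, name):
                return name
        raise KeyError(subject_id)


def normalize_channels(X: np.ndarray) -> np.ndarray:
    """Standardize each channel to zero mean and unit SD (per trial)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be N x D with N >= 2")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise DegenerateChannelError(f"constant channel(s) {bad} cannot be "
                                     "standardized")
    return (X - X.mean(axis=0)) / sd


def encode_event_labels(events: FootEvents, n_samples: int, fs: float,
                        sigma_samples: float = 5.0) -> LabelSeries:
    """Gaussian likelihood targets: ``y[n] = max_e exp(-(n-e)^2 / (2 sigma^2))``.

    Every event sample carries the exact value 1; the bump decays
    symmetrically on both sides.  Widened targets keep the MSE regression
    from collapsing onto the all-zero solution that binary impulses
    would invite.
    """
    if sigma_samples <= 0:
        raise ValueError("sigma_samples must be positive")
    n_grid = np.arange(n_samples, dtype=float)

    def encode(sample_idx: np.ndarray) -> np.ndarray:
        if np.any((sample_idx < 0) | (sample_idx >= n_samples)):
            raise ValueError("event sample outside the trial")
        y = np.zeros(n_samples)
        for e in sample_idx:
            y = np.maximum(y, np.exp(-0.5 * ((n_grid - e) / sigma_samples) ** 2))
        return y

    return LabelSeries(yic=encode(events.ic_samples(fs)),
                       yfc=encode(events.fc_samples(fs)), fs=fs)


def make_windows(X: np.ndarray, y: np.ndarray, trial_id: str = "trial",
                 window: int = 400, overlap: float = 0.5) -> WindowSet:
    """Cut one trial into overlapping fixed-length windows.

    Hop = ``window * (1 - overlap)``; windows start at multiples of the
    hop and lie fully inside the trial, so
    ``M = floor((N - window) / hop) + 1`` for ``N >= window``.  Trailing
    samples not covered by the last window are dropped (training only;
    inference consumes complete trials).  A trial shorter than one
    window yields an empty set with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if len(X) != len(y):
        raise ValueError("X and y must have the same length")
    hop = max(1, int(round(window * (1 - overlap))))
    n = len(X)
    if n < window:
        warnings.warn(f"trial {trial_id!r} shorter than one window "
                      f"({n} < {window}); no windows produced")
        starts = np.array([], dtype=int)
    else:
        m = (n - window) // hop + 1
        starts = hop * np.arange(m)
    return WindowSet(
        windows=np.stack([X[s:s + window] for s in starts]) if len(starts)
        else np.empty((0, window, X.shape[1])),
        targets=np.stack([y[s:s + window] for s in starts]) if len(starts)
        else np.empty((0, window, y.shape[1])),
        trial_ids=np.array([trial_id] * len(starts)),
        start_samples=starts, window=window, overlap=overlap)


def concat_window_sets(sets: list[WindowSet]) -> WindowSet:
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no non-empty window sets to concatenate")
    first = sets[0]
    return WindowSet(windows=np.concatenate([s.windows for s in sets]),
                     targets=np.concatenate([s.targets for s in sets]),
                     trial_ids=np.concatenate([s.trial_ids for s in sets]),
                     start_samples=np.concatenate([s.start_samples for s in sets]),
                     window=first.window, overlap=first.overlap)


def split_cohort(cohort: list[SubjectSpec],
                 fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                 seed: int = 0) -> DatasetSplit:
    """Random subject-level split stratified by group x gender.

    Within every stratum, subjects are shuffled and allocated to
    train/validation/test by largest-remainder rounding of the target
    fractions, so each stratum's proportions are within one subject of
    the targets and no subject ever appears in two sets.  Strata smaller
    than the number of sets are assigned randomly (with a warning).
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,) or np.any(fractions < 0):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, str], list[str]] = {}
    for s in cohort:
        strata.setdefault((s.group, s.gender), []).append(s.subject_id)

    sets: tuple[list[str], ...] = ([], [], [])
    for key in sorted(strata):
        ids = sorted(strata[key])
        rng.shuffle(ids)
        k = len(ids)
        if k < 3:
            warnings.warn(f"stratum {key} has only {k} subject(s); "
                          "assigning randomly")
            for sid in ids:
                sets[rng.choice(3, p=fractions)].append(sid)
            continue
        quota = fractions * k
        counts = np.floor(quota).astype(int)
        remainder = quota - counts
        for j in np.argsort(-remainder)[: k - counts.sum()]:
            counts[j] += 1
        pos = 0
        for j in range(3):
            sets[j].extend(ids[pos:pos + counts[j]])
            pos += counts[j]

    return DatasetSplit(train=sorted(sets[0]), validation=sorted(sets[1]),
                        test=sorted(sets[2]),
                        strata={s.subject_id: f"{s.group}/{s.gender}"
                                for s in cohort})
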