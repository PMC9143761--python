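"""Gait event containers.

A gait cycle of one foot is delimited by two successive initial contacts
(IC, heel strike); the final contact (FC, toe off) in between splits the
cycle into a stance and a swing phase.  Events are stored per foot as
ascending times in seconds; sample indices are derived from the sampling
frequency on demand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FootEvents", "GaitEvents", "SequencingError"]


class SequencingError(ValueError):
    """Raised when a foot's IC/FC sequence does not alternate."""


@dataclass
class FootEvents:
    """IC and FC times (seconds, ascending) of a single foot."""

    ic_times: np.ndarray
    fc_times: np.ndarray

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        for name, t in (("IC", self.ic_times), ("FC", self.fc_times)):
            if t.ndim != 1:
                raise ValueError(f"{name} times must be 1-D")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} times must be strictly ascending")

    def ic_samples(self, fs: float) -> np.ndarray:
        return np.rint(self.ic_times * fs).astype(int)

    def fc_samples(self, fs: float) -> np.ndarray:
        return np.rint(self.fc_times * fs).astype(int)

    def interleaved(self) -> list[tuple[float, str]]:
        """All events of this foot as (time, kind) sorted by time."""
        ev = [(t, "IC") for t in self.ic_times] + [(t, "FC") for t in self.fc_times]
        ev.sort()
        return ev

    def check_alternation(self) -> None:
        """Require the merged sequence to strictly alternate IC/FC."""
        kinds = [k for _, k in self.interleaved()]
        for a, b in zip(kinds, kinds[1:]):
            if a == b:
                raise SequencingError(f"two successive {a} events with no "
                                      f"{'FC' if a == 'IC' else 'IC'} in between")

    @property
    def n_events(self) -> int:
        return len(self.ic_times) + len(self.fc_times)


@dataclass
class GaitEvents:
    """Per-foot gait events of one trial."""

    feet: dict[str, FootEvents] = field(default_factory=dict)
    fs: float = 200.0

    def __getitem__(self, foot: str) -> FootEvents:
        return self.feet[foot]

    def to_dict(self) -> dict:
        return {
            foot: {"IC_s": np.round(fe.ic_times, 9).tolist(),
                   "FC_s": np.round(fe.fc_times, 9).tolist()}
            for foot, fe in self.feet.items()
        }

    @classmethod
    def from_dict(cls, d: dict, fs: float = 200.0) -> "GaitEvents":
        feet = {foot: FootEvents(np.asarray(v["IC_s"]), np.asarray(v["FC_s"]))
                for foot, v in d.items()}
        return cls(feet=feet, fs=fs)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path, fs: float = 200.0) -> "GaitEvents":
        return cls.from_dict(json.loads(Path(path).read_text()), fs=fs)
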