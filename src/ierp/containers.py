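"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelLayout", "EpochSet"]


@dataclass
class ChannelLayout:
    """Channel labels with 3-D Cartesian coordinates in millimetres."""

    labels: list[str]
    coords: np.ndarray  # (n_channels, 3), mm

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.coords.shape != (len(self.labels), 3):
            raise ValueError("coords must be (n_channels, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class EpochSet:
    """Epoched data: trials x channels x time, with metadata.

    Values are in microvolts; the time axis is event-relative in seconds
    with the event at t = 0 and uniform spacing 1/fs.
    """

    data: np.ndarray                  # (n_trials, n_channels, n_times), µV
    fs: float
    times: np.ndarray                 # (n_times,), s
    conditions: np.ndarray            # (n_trials,), condition label per trial
    subject: str = "S01"
    layout: ChannelLayout | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if np.isnan(self.data).any():
            raise ValueError("epoch data contains NaN")
        n_trials, n_channels, n_times = self.data.shape
        if self.times.shape != (n_times,):
            raise ValueError("time axis length mismatch")
        if n_times >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must be uniform at 1/fs")
        if self.conditions.shape != (n_trials,):
            raise ValueError("one condition label per trial required")
        if any(len(str(c)) == 0 for c in self.conditions):
            raise ValueError("condition labels must be nonempty")
        if self.layout is not None and self.layout.n_channels != n_channels:
            raise ValueError("layout channel count mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if str(c) not in seen:
                seen.append(str(c))
        return seen

    def select(self, condition: str) -> "EpochSet":
        """Trials of one condition, as a new EpochSet."""
        mask = self.conditions.astype(str) == str(condition)
        if not mask.any():
            raise ValueError(f"no trials with condition {condition!r}")
        return EpochSet(data=self.data[mask], fs=self.fs, times=self.times,
                        conditions=self.conditions[mask], subject=self.subject,
                        layout=self.layout, ground_truth=self.ground_truth)
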