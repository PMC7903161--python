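"""Core data carriers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np


@dataclass
class MultichannelRecording:
    """A channels x samples EEG recording in microvolts.

    ``events`` are ``(sample_index, code)`` pairs with 0-based sample
    indices; intervals throughout the package are half-open.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_positions: Optional[np.ndarray] = None
    events: list[tuple[int, int]] = field(default_factory=list)
    bad_channels: set[str] = field(default_factory=set)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        for s, _ in self.events:
            if not 0 <= s < self.n_samples:
                raise ValueError(f"event sample {s} outside [0, {self.n_samples})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self, data: Optional[np.ndarray] = None) -> "MultichannelRecording":
        return replace(
            self,
            data=np.array(self.data if data is None else data),
            channel_labels=list(self.channel_labels),
            channel_positions=None if self.channel_positions is None
            else np.array(self.channel_positions),
            events=list(self.events),
            bad_channels=set(self.bad_channels),
            meta=dict(self.meta),
        )

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        lut = {lb: i for i, lb in enumerate(self.channel_labels)}
        missing = [lb for lb in labels if lb not in lut]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        return np.array([lut[lb] for lb in labels], dtype=int)

    def pick(self, labels: Sequence[str]) -> "MultichannelRecording":
        """Return a new recording restricted to ``labels`` (given order)."""
        idx = self.index_of(labels)
        kept = [self.channel_labels[i] for i in idx]
        return MultichannelRecording(
            data=np.array(self.data[idx]),
            fs=self.fs,
            channel_labels=kept,
            channel_positions=None if self.channel_positions is None
            else np.array(self.channel_positions[idx]),
            events=list(self.events),
            bad_channels={lb for lb in self.bad_channels if lb in kept},
            meta=dict(self.meta),
        )

    def drop_channels(self, labels: Sequence[str]) -> "MultichannelRecording":
        keep = [lb for lb in self.channel_labels if lb not in set(labels)]
        if not keep:
            raise ValueError("dropping all channels leaves an unusable recording")
        return self.pick(keep)

    def good_channels(self) -> list[str]:
        return [lb for lb in self.channel_labels if lb not in self.bad_channels]


@dataclass
class Epochs:
    """Trials x channels x samples segments cut from one recording."""

    data: np.ndarray
    fs: float
    t0_offsets: np.ndarray
    duration: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.t0_offsets = np.asarray(self.t0_offsets, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        if len(self.t0_offsets) != self.data.shape[0]:
            raise ValueError("one onset per trial required")
        if np.any(np.diff(self.t0_offsets) <= 0) and len(self.t0_offsets) > 1:
            raise ValueError("trials must be ordered by onset")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]
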