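"""Single-trial SSVEP amplitude/phase extraction and phase-locking.

The analytic signal is always computed on the full-length narrowband
series *before* epoching (edge artifacts of the Hilbert transform stay at
the recording boundaries instead of inside trials). Per-trial phase is the
circular mean of the per-sample phase difference to the flicker reference,
which is defined to have zero phase at each trial onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.signal import hilbert

from .recording import Epochs

_DEGENERATE_RESULTANT = 1e-3


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return -np.mod(-np.asarray(phi) + np.pi, 2 * np.pi) + np.pi


def analytic_signal(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Envelope and instantaneous phase of a narrowband series.

    Works on a 1-D series or a channels x samples matrix (last axis =
    time). Raises on (near-)constant input, whose phase is undefined.
    """
    x = np.asarray(series, dtype=float)
    if np.ptp(x, axis=-1).min() == 0:
        raise ValueError("constant input: instantaneous phase undefined")
    n = x.shape[-1]
    nfast = sp_fft.next_fast_len(n, real=False)
    z = hilbert(x, N=nfast, axis=-1)[..., :n]
    return np.abs(z), np.angle(z)


def flicker_phase(
    onset_sample: int, fs: float, f: float, length: int
) -> np.ndarray:
    """Reference phase series ``wrap(2*pi*f*(n - onset)/fs)``, zero at onset."""
    n = np.arange(length)
    return wrap_phase(2 * np.pi * f * (n - onset_sample) / fs)


@dataclass
class TrialTable:
    """One amplitude / phase-difference pair per trial, for one condition."""

    amplitude: np.ndarray  # uV, >= 0
    phase_diff: np.ndarray  # radians in (-pi, pi], EEG minus flicker
    valid: np.ndarray  # False where the circular mean was degenerate
    condition: str = ""
    channel: str = "virtual_occipital"

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase_diff = np.asarray(self.phase_diff, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.amplitude.shape == self.phase_diff.shape == self.valid.shape):
            raise ValueError("per-trial arrays must have equal length")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.amplitude.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "condition": self.condition,
                "amplitude_uV": self.amplitude,
                "phase_diff_rad": self.phase_diff,
                "valid": self.valid,
            }
        )


@dataclass(frozen=True)
class PlvResult:
    plv: float
    n_trials: int
    mean_angle: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.plv <= 1.0 + 1e-12:
            raise ValueError("PLV must lie in [0, 1]")


def circular_mean(phases: np.ndarray) -> tuple[float, float]:
    """Resultant angle and resultant length of a sample of angles."""
    z = np.exp(1j * np.asarray(phases)).mean()
    return float(np.angle(z)), float(np.abs(z))


def single_trial_metrics(
    envelope: np.ndarray,
    phase: np.ndarray,
    onsets: Sequence[int],
    fs: float,
    flicker_freq: float,
    duration: float = 2.0,
    condition: str = "",
    channel: str = "virtual_occipital",
) -> TrialTable:
    """Reduce full-length envelope/phase series to one value per trial.

    ``envelope`` and ``phase`` must come from :func:`analytic_signal`
    applied to the unsegmented narrowband series. Amplitude is the
    arithmetic mean of the envelope in ``[onset, onset + duration*fs)``;
    phase is the circular mean of the wrapped per-sample difference to the
    flicker reference. Trials with a degenerate resultant are flagged
    invalid (and should be excluded from PLV).
    """
    envelope = np.asarray(envelope, dtype=float)
    phase = np.asarray(phase, dtype=float)
    n_win = int(round(duration * fs))
    # reference phase within a trial is onset-relative, identical per trial
    ref = wrap_phase(2 * np.pi * flicker_freq * np.arange(n_win) / fs)
    amps, diffs, valid = [], [], []
    for onset in onsets:
        if onset + n_win > envelope.size:
            warnings.warn("truncated trial dropped", stacklevel=2)
            continue
        sl = slice(onset, onset + n_win)
        amps.append(envelope[sl].mean())
        ang, r = circular_mean(wrap_phase(phase[sl] - ref))
        if r < _DEGENERATE_RESULTANT:
            warnings.warn(
                "degenerate circular mean within a trial: flagged invalid",
                stacklevel=2,
            )
            valid.append(False)
            diffs.append(np.nan)
        else:
            valid.append(True)
            diffs.append(ang)
    return TrialTable(
        amplitude=np.array(amps),
        phase_diff=np.array(diffs),
        valid=np.array(valid, dtype=bool),
        condition=condition,
        channel=channel,
    )


def phase_locking_value(trial_phases: np.ndarray) -> PlvResult:
    """Modulus (and angle) of the mean unit phasor across trials."""
    phases = np.asarray(trial_phases, dtype=float)
    phases = phases[np.isfinite(phases)]
    if phases.size < 2:
        raise ValueError("PLV requires at least 2 trials")
    z = np.exp(1j * phases).mean()
    # |z| can exceed 1 by float epsilon for perfectly aligned phases
    return PlvResult(plv=min(float(np.abs(z)), 1.0), n_trials=int(phases.size),
                     mean_angle=float(np.angle(z)))


def evoked_response(epochs: Epochs) -> np.ndarray:
    """Pointwise trial average, channels x samples."""
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    return epochs.data.mean(axis=0)


def trial_table(
    narrowband_series: np.ndarray,
    onsets: Sequence[int],
    fs: float,
    flicker_freq: float,
    duration: float = 2.0,
    condition: str = "",
) -> TrialTable:
    """Convenience: analytic signal of a full-length series, then metrics."""
    env, phase = analytic_signal(narrowband_series)
    return single_trial_metrics(
        env, phase, onsets, fs, flicker_freq, duration, condition=condition
    )
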