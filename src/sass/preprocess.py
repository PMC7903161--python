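"""Channel quality control, FIR filtering, epoching, virtual channel.

Conventions fixed package-wide: 0-based sample indexing, half-open
intervals, phase in radians in (-pi, pi]. Filtering is zero-phase because
single-trial phase is a downstream endpoint and uncompensated group delay
would bias it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .layout import OCCIPITAL_LABELS
from .recording import Epochs, MultichannelRecording


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass FIR specification (Hamming window design)."""

    low: float
    high: float
    n_taps: Optional[int] = None
    transition: float = 2.0
    window: str = "hamming"

    def validate(self, fs: float) -> None:
        if not 0 < self.low < self.high < fs / 2:
            raise ValueError(
                f"band edges must satisfy 0 < low < high < fs/2, got "
                f"({self.low}, {self.high}) at fs={fs}"
            )
        if self.n_taps is not None and self.n_taps % 2 == 0:
            raise ValueError("n_taps must be odd (linear-phase type I)")


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design a linear-phase type-I bandpass kernel.

    When ``n_taps`` is unset, the length follows the Hamming window-method
    rule of thumb ``~3.3 / (transition / fs)``, rounded up to odd.
    """
    spec.validate(fs)
    n_taps = spec.n_taps
    if n_taps is None:
        n_taps = int(np.ceil(3.3 * fs / spec.transition))
        if n_taps % 2 == 0:
            n_taps += 1
    return signal.firwin(
        n_taps, [spec.low, spec.high], pass_zero=False, window=spec.window, fs=fs
    )


def filter_recording(
    rec: MultichannelRecording, kernel: np.ndarray
) -> MultichannelRecording:
    """Zero-phase FIR filtering of every channel; length preserved.

    The symmetric kernel is applied once via FFT overlap-add with the group
    delay compensated exactly (odd-length linear-phase kernel), after
    reflect-padding by one kernel length to bound edge transients.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size % 2 == 0:
        raise ValueError("kernel must be a 1-D odd-length FIR")
    if rec.n_samples < 3 * kernel.size:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than 3x kernel "
            f"({kernel.size} taps)"
        )
    pad = kernel.size
    x = np.pad(rec.data, ((0, 0), (pad, pad)), mode="reflect")
    y = _fft_convolve_same(x, kernel)
    return rec.copy(data=y[:, pad:-pad])


def _fft_convolve_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Centered ('same') FFT convolution along the last axis.

    Pads to a fast FFT length: plain oaconvolve can pick catastrophically
    slow transform sizes for typical recording lengths.
    """
    n = x.shape[-1]
    m = kernel.size
    nfast = sp_fft.next_fast_len(n + m - 1, real=True)
    spec = sp_fft.rfft(x, nfast, axis=-1) * sp_fft.rfft(kernel, nfast)
    full = sp_fft.irfft(spec, nfast, axis=-1)
    half = (m - 1) // 2
    return full[..., half : half + n]


def filter_data(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-phase filtering of a bare 1-D or 2-D (channels x samples) array."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    pad = kernel.size
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    y = _fft_convolve_same(xp, np.asarray(kernel, dtype=float))[:, pad:-pad]
    return y[0] if y.shape[0] == 1 else y


def broadband_power(
    rec: MultichannelRecording, band: tuple[float, float] = (1.0, 124.0)
) -> np.ndarray:
    """Per-channel variance of the band-filtered signal, in uV^2."""
    low, high = band
    high = min(high, rec.fs / 2 * 0.996)
    kernel = design_fir(FilterSpec(low, high), rec.fs)
    if rec.n_samples < 3 * kernel.size:
        # short recording: fall back to a proportionally shorter kernel
        n_taps = max(3, (rec.n_samples // 3) | 1)
        kernel = design_fir(FilterSpec(low, high, n_taps=n_taps), rec.fs)
    filtered = filter_data(rec.data, kernel)
    return np.var(np.atleast_2d(filtered), axis=1)


def _saturated(
    x: np.ndarray, lo: float, hi: float, min_run: int, tol: float
) -> bool:
    at_rail = (x >= hi - tol) | (x <= lo + tol)
    if not at_rail.any():
        return False
    # longest run of rail-pinned samples
    padded = np.concatenate(([False], at_rail, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = edges[1::2] - edges[0::2]
    return bool(runs.size and runs.max() >= min_run)


def exclude_bad_channels(
    rec_no_stim: MultichannelRecording,
    power_factor: float = 100.0,
    saturation_run: int = 10,
) -> set[str]:
    """Identify channels to drop, from the stimulation-free condition only.

    A channel is excluded when its broadband (1-124 Hz) power exceeds
    ``power_factor`` (two orders of magnitude) times the median across
    channels, or when it pins the recording's physical extremes for
    ``saturation_run`` consecutive samples. The returned label set is meant
    to be applied to both conditions.
    """
    if rec_no_stim.n_channels < 3:
        raise ValueError("need at least 3 channels for quality control")
    power = broadband_power(rec_no_stim)
    median = np.median(power)
    bad = {
        lb
        for lb, p in zip(rec_no_stim.channel_labels, power)
        if median > 0 and p > power_factor * median
    }
    lo = rec_no_stim.meta.get("phys_min", float(rec_no_stim.data.min()))
    hi = rec_no_stim.meta.get("phys_max", float(rec_no_stim.data.max()))
    tol = rec_no_stim.meta.get("lsb", (hi - lo) / 2**16 if hi > lo else 0.0)
    for i, lb in enumerate(rec_no_stim.channel_labels):
        if lb in bad:
            continue
        if _saturated(rec_no_stim.data[i], lo, hi, saturation_run, tol):
            bad.add(lb)
    if len(bad) == rec_no_stim.n_channels:
        raise ValueError("all channels excluded: unusable recording")
    return bad


def epoch(rec: MultichannelRecording, duration: float = 2.0) -> Epochs:
    """Cut ``[onset, onset + duration * fs)`` segments at every event.

    Trials whose window would run past the end of the recording are dropped
    with a warning; overlapping trials are an error.
    """
    n_win = int(round(duration * rec.fs))
    onsets = sorted(s for s, _ in rec.events)
    kept = [s for s in onsets if s + n_win <= rec.n_samples]
    if len(kept) < len(onsets):
        warnings.warn(
            f"dropped {len(onsets) - len(kept)} truncated trial(s)", stacklevel=2
        )
    if not kept:
        warnings.warn("no events: empty epochs", stacklevel=2)
        return Epochs(
            np.empty((0, rec.n_channels, n_win)), rec.fs, np.empty(0, int),
            duration, list(rec.channel_labels),
        )
    if np.any(np.diff(kept) < n_win):
        raise ValueError("overlapping trials")
    data = np.stack([rec.data[:, s : s + n_win] for s in kept])
    return Epochs(data, rec.fs, np.array(kept), duration, list(rec.channel_labels))


def virtual_occipital(
    obj: Union[MultichannelRecording, Epochs],
    occipital_labels: Sequence[str] = OCCIPITAL_LABELS,
) -> np.ndarray:
    """Unweighted mean over the available (non-excluded) occipital channels.

    Returns a 1-D series for a recording, or trials x samples for epochs.
    """
    if isinstance(obj, MultichannelRecording):
        labels, bad = obj.channel_labels, obj.bad_channels
    else:
        labels, bad = obj.channel_labels, set()
    avail = [lb for lb in occipital_labels if lb in labels and lb not in bad]
    if not avail:
        raise ValueError("no occipital channel available")
    lut = {lb: i for i, lb in enumerate(labels)}
    idx = np.array([lut[lb] for lb in avail])
    if isinstance(obj, MultichannelRecording):
        return obj.data[idx].mean(axis=0)
    return obj.data[:, idx, :].mean(axis=1)
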