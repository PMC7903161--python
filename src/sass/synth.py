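"""Synthetic concurrent EEG / AM-tACS sessions with known ground truth.

A session pair consists of a stimulation-free recording (occipital 10 Hz
flicker response + spatially correlated 1/f noise) and a during-stimulation
recording that adds a transduced stimulation artifact. The artifact is an
amplitude-modulated waveform ``m(t) = (1 + cos(2*pi*f_env*t))/2 *
sin(2*pi*f_carrier*t)`` generated at an oversampled rate, scaled per channel,
passed through a memoryless polynomial nonlinearity (which demodulates the
envelope into components at f_env and its harmonics, each with its own
topography), lowpass filtered at the recording chain's anti-aliasing cutoff
and decimated to the recording rate. The carrier itself does not survive
this chain; only demodulation products below the cutoff do.

Flicker onsets are spaced by an inter-trial interval drawn uniformly from a
range spanning an integer number of envelope cycles, so onset phase relative
to the stimulation envelope is uniform and the artifact destroys any
consistent flicker-EEG phase relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .layout import OCCIPITAL_LABELS, standard_layout
from .preprocess import FilterSpec, design_fir, filter_data
from .recording import MultichannelRecording

#: Anti-aliasing cutoff of the emulated recording chain, Hz.
ANTIALIAS_HZ = 125.0
#: Oversampling factor for generating the carrier before transduction.
OVERSAMPLE = 8

_SSVEP_WEIGHTS = {
    "Oz": 1.0, "O1": 0.8, "O2": 0.8, "POz": 0.65, "PO3": 0.5, "PO4": 0.5,
    "PO7": 0.35, "PO8": 0.35, "Iz": 0.4, "Pz": 0.25, "P1": 0.15, "P2": 0.15,
}


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one simulated two-session experiment."""

    n_channels: int = 64
    fs: float = 500.0
    n_trials: int = 200
    trial_duration: float = 2.0
    iti_range: tuple[float, float] = (0.5, 1.0)
    flicker_freq: float = 10.0
    carrier_freq: float = 220.0
    artifact_gain: float = 1e3
    ssvep_amp: float = 3.0
    ssvep_phase_lag: float = np.pi / 4
    amp_jitter_sigma: float = 0.2
    noise_exponent: float = 1.0
    noise_rms: float = 1.5
    nonlinearity_coeffs: tuple[float, ...] = (1.0, 0.1, 0.02, 0.05)
    harmonic_topo_jitter: float = 0.8
    n_artifact_sources: int = 1
    source_freq_spread: float = 0.15
    bad_power_channels: tuple[str, ...] = ()
    bad_power_factor: float = 150.0
    saturated_channels: tuple[str, ...] = ()
    edge_margin: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        cycles = self.trial_duration * self.flicker_freq
        if abs(cycles - round(cycles)) > 1e-9:
            raise ValueError(
                "trial_duration * flicker_freq must be an integer cycle count"
            )
        lo, hi = self.iti_range
        if lo < 0:
            raise ValueError("iti lower bound must be >= 0")
        if hi < lo:
            raise ValueError("iti upper bound below lower bound")
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")
        if self.fs <= 0 or self.n_trials < 1:
            raise ValueError("fs and n_trials must be positive")
        if self.n_artifact_sources < 1:
            raise ValueError("need at least one artifact source")


@dataclass
class GroundTruth:
    """Hidden state of a generated session pair, for parameter recovery."""

    ssvep_topography: np.ndarray
    artifact_topographies: dict[int, np.ndarray]
    true_trial_amplitudes: dict[str, np.ndarray]
    true_trial_phases: dict[str, np.ndarray]
    onset_samples: dict[str, np.ndarray]
    ssvep_waveforms: dict[str, np.ndarray]
    artifact: Optional[np.ndarray] = None
    artifact_scale: float = 0.0
    config: Optional[SessionConfig] = None

    def validate(self) -> None:
        cfg = self.config
        for cond, onsets in self.onset_samples.items():
            if len(self.true_trial_amplitudes[cond]) != len(onsets):
                raise ValueError("one amplitude per trial required")
            if len(self.true_trial_phases[cond]) != len(onsets):
                raise ValueError("one phase per trial required")
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if cfg is not None:
                min_gap = (cfg.trial_duration + cfg.iti_range[0]) * cfg.fs
                if len(onsets) > 1 and np.min(np.diff(onsets)) < min_gap - 1:
                    raise ValueError("onsets closer than trial + minimum ITI")


def _draw_onsets(config: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    itis = rng.uniform(*config.iti_range, size=config.n_trials)
    t = config.edge_margin + np.concatenate(
        ([0.0], np.cumsum(config.trial_duration + itis[:-1]))
    )
    return np.round(t * config.fs).astype(int)


def _session_length(config: SessionConfig, onsets: np.ndarray) -> int:
    end = onsets[-1] / config.fs + config.trial_duration + config.edge_margin
    return int(np.ceil(end * config.fs))


def ssvep_component(
    onsets: np.ndarray,
    config: SessionConfig,
    n_samples: int,
    labels: Sequence[str],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gated flicker-locked sinusoid and its occipital topography.

    Returns ``(waveform, topography, trial_amplitudes, trial_phases)``. The
    waveform is zero outside trial windows; within trial i it is
    ``a_i * cos(2*pi*f*(n - onset_i)/fs + phase_lag)`` with log-normal
    amplitude jitter around ``ssvep_amp``. The topography has unit norm and
    is concentrated on the occipital channel group.
    """
    onsets = np.asarray(onsets, dtype=int)
    topo = np.array([_SSVEP_WEIGHTS.get(lb, 0.05) for lb in labels], dtype=float)
    topo /= np.linalg.norm(topo)
    waveform = np.zeros(n_samples)
    if onsets.size == 0:
        warnings.warn("no onsets: SSVEP waveform is identically zero",
                      stacklevel=2)
        return waveform, topo, np.empty(0), np.empty(0)
    if onsets.min() < 0 or onsets.max() >= n_samples:
        raise ValueError("onsets outside the recording")
    n_win = int(round(config.trial_duration * config.fs))
    sigma = config.amp_jitter_sigma
    amps = config.ssvep_amp * np.exp(
        sigma * rng.standard_normal(onsets.size) - sigma**2 / 2
    )
    phases = np.full(onsets.size, config.ssvep_phase_lag)
    tau = np.arange(n_win) / config.fs
    carrier = 2 * np.pi * config.flicker_freq * tau
    for onset, a, ph in zip(onsets, amps, phases):
        stop = min(onset + n_win, n_samples)
        waveform[onset:stop] = a * np.cos(carrier[: stop - onset] + ph)
    return waveform, topo, amps, phases


def _stimulation_gain_pattern(
    labels: Sequence[str], positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Artifact gain per channel, peaked between the stimulation electrodes."""
    lut = {lb: i for i, lb in enumerate(labels)}
    anchors = [lut[lb] for lb in ("CPz", "Iz") if lb in lut]
    center = positions[anchors].mean(axis=0) if anchors else np.array([0, -1.0, 0.3])
    d2 = np.sum((positions - center) ** 2, axis=1)
    base = np.exp(-d2 / (2 * 0.6**2)) + 0.1
    return base * (1.0 + 0.05 * rng.standard_normal(len(labels)))


def _smooth_pattern(positions: np.ndarray, rng: np.random.Generator,
                    scale: float = 0.5) -> np.ndarray:
    """Zero-mean spatially smooth random pattern with unit std."""
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    kernel = np.exp(-d2 / (2 * scale**2))
    pat = kernel @ rng.standard_normal(positions.shape[0])
    pat -= pat.mean()
    std = pat.std()
    return pat / std if std > 0 else pat


def _artifact_components(
    config: SessionConfig,
    n_samples: int,
    labels: Sequence[str],
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mixing weights and demodulated time courses.

    Returns ``(weights, courses)`` with shapes (n_channels, K) and
    (K, n_samples) so that the recorded artifact is ``weights @ courses``.
    One block of polynomial orders per artifact source; extra sources get a
    small envelope-frequency offset so their time courses are linearly
    independent of the primary one.
    """
    coeffs = np.asarray(config.nonlinearity_coeffs, dtype=float)
    if coeffs.size == 0 or not np.any(coeffs):
        warnings.warn("all nonlinearity coefficients zero: no recorded artifact",
                      stacklevel=3)
        return (np.zeros((len(labels), 1)), np.zeros((1, n_samples)))
    if not np.any(coeffs[1::2]):
        warnings.warn(
            "no even-order nonlinearity: the recorded artifact has no "
            "envelope-frequency component for SASS to remove", stacklevel=3
        )
    fs_os = config.fs * OVERSAMPLE
    n_os = n_samples * OVERSAMPLE
    # FIR lowpass emulating the anti-aliasing filter before decimation;
    # the waveform is generated with a discard margin on both sides so
    # filter edge transients (reflected carrier) never enter the session
    lp = design_fir_lowpass(ANTIALIAS_HZ, fs_os)
    n_pad = lp.size
    t = (np.arange(n_os + 2 * n_pad) - n_pad) / fs_os
    n_src = config.n_artifact_sources
    offsets = config.source_freq_spread * (np.arange(n_src) - (n_src - 1) / 2)
    if n_src % 2 == 0:
        offsets -= offsets[0]  # keep one source exactly at the envelope freq
    all_weights, all_courses = [], []
    for s in range(n_src):
        f_env = config.flicker_freq + offsets[s]
        phi = rng.uniform(0, 2 * np.pi)
        envelope = 0.5 * (1.0 + np.cos(2 * np.pi * f_env * t + phi))
        m = envelope * np.sin(2 * np.pi * config.carrier_freq * t
                              + rng.uniform(0, 2 * np.pi))
        gain = _stimulation_gain_pattern(labels, positions, rng)
        power = np.ones_like(m)
        for order, c in enumerate(coeffs, start=1):
            power = power * m
            if c == 0:
                continue
            filtered = filter_data(power, lp)[n_pad : n_pad + n_os : OVERSAMPLE]
            filtered = filtered - filtered.mean()
            if order == 1:
                topo_jitter = np.ones(len(labels))
            else:
                topo_jitter = np.abs(
                    1.0 + config.harmonic_topo_jitter
                    * _smooth_pattern(positions, rng)
                )
            all_weights.append(c * topo_jitter * gain**order)
            all_courses.append(filtered)
    weights = np.stack(all_weights, axis=1)
    courses = np.stack(all_courses, axis=0)
    return weights, courses


def design_fir_lowpass(cutoff: float, fs: float, n_taps: int = 1025) -> np.ndarray:
    """Steep anti-aliasing lowpass (~100 dB stopband).

    The stopband floor matters: the raw carrier is orders of magnitude
    above the demodulated components, so a -53 dB floor would leave a
    spurious in-band carrier residue after decimation.
    """
    from scipy import signal

    return signal.firwin(n_taps, cutoff, window=("kaiser", 10.0), fs=fs)


def am_tacs_artifact(
    config: SessionConfig,
    duration: float,
    labels: Optional[Sequence[str]] = None,
    positions: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Recorded (transduced, anti-aliased, decimated) artifact matrix.

    The output is unscaled: :func:`generate_session` rescales it so the
    band-limited artifact-to-SSVEP RMS ratio on the worst channel equals
    ``artifact_gain``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    config.validate()
    if labels is None or positions is None:
        labels, positions = standard_layout(config.n_channels)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_samples = int(round(duration * config.fs))
    weights, courses = _artifact_components(config, n_samples, labels,
                                            positions, rng)
    return weights @ courses


def background_noise(
    config: SessionConfig,
    duration: float,
    rng: Optional[np.random.Generator] = None,
    positions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Spatially correlated 1/f^exponent noise floor, ``noise_rms`` per channel."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_channels
    n_samples = int(round(duration * config.fs))
    if positions is None:
        _, positions = standard_layout(n)
    from scipy import fft as sp_fft

    white = rng.standard_normal((n, n_samples))
    nfast = sp_fft.next_fast_len(n_samples, real=True)
    freqs = np.fft.rfftfreq(nfast, 1.0 / config.fs)
    shape = np.maximum(freqs, 1.0) ** (-config.noise_exponent / 2.0)
    shape[0] = 0.0
    sources = sp_fft.irfft(
        sp_fft.rfft(white, nfast, axis=1) * shape, nfast, axis=1
    )[:, :n_samples]
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    mixing = (np.exp(-d2 / (2 * 0.18**2)) + 0.4 * np.eye(n)
              + 0.05 * rng.standard_normal((n, n)))
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    noise = mixing @ sources
    rms = noise.std(axis=1, keepdims=True)
    return noise / rms * config.noise_rms


def ecg_locked_modulation(
    config: SessionConfig,
    r_peak_times: Sequence[float],
    n_samples: int,
    height: float = 0.0,
    width: float = 0.3,
) -> np.ndarray:
    """Multiplicative artifact gain trace, 1 + a bump at each R-peak.

    With ``height = 0`` (the default, matching the null finding for
    AM-tACS) the gain is identically 1. Bumps are Hann-shaped with total
    ``width`` seconds; overlapping bumps add, with a warning.
    """
    r_peak_times = np.asarray(r_peak_times, dtype=float)
    if np.any(np.diff(r_peak_times) < 0):
        raise ValueError("r_peak_times must be sorted")
    gain = np.ones(n_samples)
    if height == 0.0 or r_peak_times.size == 0:
        return gain
    if r_peak_times.size > 1 and np.min(np.diff(r_peak_times)) < width:
        warnings.warn("overlapping R-peak bumps are summed", stacklevel=2)
    t = np.arange(n_samples) / config.fs
    for tr in r_peak_times:
        sel = np.abs(t - tr) < width / 2
        gain[sel] += height * 0.5 * (1 + np.cos(2 * np.pi * (t[sel] - tr) / width))
    return gain


def generate_session(
    config: SessionConfig,
) -> tuple[MultichannelRecording, MultichannelRecording, GroundTruth]:
    """Generate the stimulation-free and during-stimulation session pair.

    Both recordings share channel labels/positions and trial-structure
    statistics but have independent noise, trial timing, and SSVEP
    amplitude draws. The stimulation recording is the sum of a
    no-stim-style brain+noise signal and the scaled artifact matrix
    (additivity holds exactly: ``stim - truth.artifact`` is brain+noise).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels, positions = standard_layout(config.n_channels)

    onsets = {c: _draw_onsets(config, rng) for c in ("no_stim", "stim")}
    n_samp = {c: _session_length(config, onsets[c]) for c in onsets}

    waveforms, amps, phases = {}, {}, {}
    topo = None
    recordings = {}
    for cond in ("no_stim", "stim"):
        wave, topo, a, ph = ssvep_component(
            onsets[cond], config, n_samp[cond], labels, rng
        )
        waveforms[cond], amps[cond], phases[cond] = wave, a, ph
        noise = background_noise(config, n_samp[cond] / config.fs, rng,
                                 positions=positions)
        recordings[cond] = topo[:, None] * wave[None, :] + noise

    # scale the artifact to the requested narrowband gain on the worst channel
    weights, courses = _artifact_components(
        config, n_samp["stim"], labels, positions, rng
    )
    band = (config.flicker_freq - 1.0, config.flicker_freq + 1.0)
    kernel = design_fir(FilterSpec(*band), config.fs)
    courses_f = np.atleast_2d(filter_data(courses, kernel))
    gram = courses_f @ courses_f.T / courses_f.shape[1]
    chan_band_power = np.einsum("ck,kl,cl->c", weights, gram, weights)
    worst_rms = np.sqrt(chan_band_power.max())
    ssvep_band_rms = np.std(filter_data(waveforms["stim"], kernel)) * np.abs(topo).max()
    if worst_rms > 0 and ssvep_band_rms > 0:
        scale = config.artifact_gain * ssvep_band_rms / worst_rms
    else:
        scale = 0.0
    artifact = scale * (weights @ courses)
    recordings["stim"] = recordings["stim"] + artifact

    # per-harmonic artifact topographies (principal direction per band)
    harmonic_topos: dict[int, np.ndarray] = {}
    for h in (1, 2, 3):
        f = config.flicker_freq * h
        if f + 1.0 >= config.fs / 2:
            continue
        kern_h = design_fir(FilterSpec(f - 1.0, f + 1.0), config.fs)
        cf = np.atleast_2d(filter_data(courses, kern_h))
        gram_h = cf @ cf.T / cf.shape[1]
        cov_h = weights @ gram_h @ weights.T
        evals, evecs = np.linalg.eigh(cov_h)
        vec = evecs[:, -1]
        if evals[-1] <= 1e-30:
            vec = np.zeros_like(vec)
        elif vec[np.argmax(np.abs(vec))] < 0:
            vec = -vec
        harmonic_topos[h] = vec

    for cond in ("no_stim", "stim"):
        bad_idx = [labels.index(lb) for lb in config.bad_power_channels]
        for i in bad_idx:
            recordings[cond][i] *= np.sqrt(config.bad_power_factor)
        for lb in config.saturated_channels:
            i = labels.index(lb)
            rail = np.abs(recordings[cond]).max()
            n_sat = int(config.fs)  # pin for one second mid-recording
            start = n_samp[cond] // 2
            recordings[cond][i, start : start + n_sat] = rail

    events = {
        cond: [(int(s), 1) for s in onsets[cond]] for cond in ("no_stim", "stim")
    }
    recs = {
        cond: MultichannelRecording(
            data=recordings[cond],
            fs=config.fs,
            channel_labels=list(labels),
            channel_positions=positions.copy(),
            events=events[cond],
        )
        for cond in ("no_stim", "stim")
    }
    truth = GroundTruth(
        ssvep_topography=topo,
        artifact_topographies=harmonic_topos,
        true_trial_amplitudes=amps,
        true_trial_phases=phases,
        onset_samples={c: np.asarray(onsets[c]) for c in onsets},
        ssvep_waveforms=waveforms,
        artifact=artifact,
        artifact_scale=scale,
        config=config,
    )
    truth.validate()
    return recs["no_stim"], recs["stim"], truth
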