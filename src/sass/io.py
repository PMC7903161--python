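"""File formats: EDF recordings, event tables, models, ground truth.

A self-contained 16-bit EDF writer/reader is included (physical units are
converted to microvolts on read). Events live in a separate two-column
tab-separated file of (onset_sample, event_code) with 0-based indices.
Fitted models persist to HDF5.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .core import SassModel
from .layout import standard_layout
from .recording import MultichannelRecording
from .synth import GroundTruth, SessionConfig

_UNIT_TO_UV = {"uV": 1.0, "mV": 1e3, "V": 1e6}


def _fmt(value: Union[float, int, str], width: int) -> bytes:
    s = str(value)
    if isinstance(value, float):
        s = f"{value:.6g}"
        if len(s) > width:
            s = f"{value:.{max(width - 7, 0)}e}"
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} characters")
    return s.ljust(width).encode("ascii")


def write_edf(rec: MultichannelRecording, path: Union[str, Path]) -> None:
    """Write a recording as 16-bit EDF (physical unit uV, 1 s records).

    The true sample count is stored in the header's reserved field so the
    final zero-padded record can be trimmed on read.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_ch, n_samples = rec.data.shape
    n_rec = int(np.ceil(n_samples / spr))

    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)

    header = b"".join([
        _fmt("0", 8),
        _fmt("X", 80),
        _fmt("synthetic", 80),
        _fmt("01.01.20", 8),
        _fmt("00.00.00", 8),
        _fmt(256 * (n_ch + 1), 8),
        _fmt(f"NSAMP={n_samples}", 44),
        _fmt(n_rec, 8),
        _fmt("1", 8),
        _fmt(n_ch, 4),
    ])
    fields = [
        [_fmt(lb, 16) for lb in rec.channel_labels],
        [_fmt("AgAgCl electrode", 80)] * n_ch,
        [_fmt("uV", 8)] * n_ch,
        [_fmt(float(v), 8) for v in pmin],
        [_fmt(float(v), 8) for v in pmax],
        [_fmt(dmin, 8)] * n_ch,
        [_fmt(dmax, 8)] * n_ch,
        [_fmt("", 80)] * n_ch,
        [_fmt(spr, 8)] * n_ch,
        [_fmt("", 32)] * n_ch,
    ]
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samples] = rec.data
    digital = np.round(
        (padded - pmin[:, None]) / scale[:, None] + dmin
    ).clip(dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        # records: per record, each signal's samples contiguously
        interleaved = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(interleaved).tobytes())


def read_edf(path: Union[str, Path]) -> MultichannelRecording:
    """Read a 16-bit EDF file; data is returned in microvolts."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF header")
        reserved = head[192:236].decode("ascii").strip()
        n_rec = int(head[236:244].decode("ascii").strip())
        rec_dur = float(head[244:252].decode("ascii").strip())
        n_ch = int(head[252:256].decode("ascii").strip())

        def block(width: int) -> list[str]:
            raw = fh.read(width * n_ch)
            return [
                raw[i * width : (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = block(16)
        block(80)  # transducer
        units = block(8)
        pmin = np.array([float(v) for v in block(8)])
        pmax = np.array([float(v) for v in block(8)])
        dmin = np.array([float(v) for v in block(8)])
        dmax = np.array([float(v) for v in block(8)])
        block(80)  # prefiltering
        spr = [int(v) for v in block(8)]
        block(32)  # reserved
        if len(set(spr)) != 1:
            raise ValueError("mixed sampling rates are not supported")
        raw = np.frombuffer(fh.read(), dtype="<i2")

    spr0 = spr[0]
    fs = spr0 / rec_dur
    expected = n_rec * n_ch * spr0
    if raw.size < expected:
        raise ValueError("truncated EDF data section")
    data = (
        raw[:expected].reshape(n_rec, n_ch, spr0).transpose(1, 0, 2)
        .reshape(n_ch, n_rec * spr0).astype(float)
    )
    gain = (pmax - pmin) / (dmax - dmin)
    phys = (data - dmin[:, None]) * gain[:, None] + pmin[:, None]
    for i, unit in enumerate(units):
        if unit not in _UNIT_TO_UV:
            raise ValueError(f"unknown physical unit {unit!r} on {labels[i]}")
        phys[i] *= _UNIT_TO_UV[unit]
    if reserved.startswith("NSAMP="):
        n_samples = int(reserved.split("=", 1)[1])
        phys = phys[:, :n_samples]
    lab64, pos64 = standard_layout(64)
    lut = dict(zip(lab64, pos64))
    positions = (
        np.array([lut[lb] for lb in labels]) if all(lb in lut for lb in labels)
        else None
    )
    return MultichannelRecording(
        data=phys, fs=fs, channel_labels=labels, channel_positions=positions,
        meta={"phys_min": float(pmin.min()), "phys_max": float(pmax.max()),
              "lsb": float(gain.max())},
    )


def write_events(events: Sequence[tuple[int, int]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("onset_sample\tcode\n")
        for sample, code in events:
            fh.write(f"{int(sample)}\t{int(code)}\n")


def read_events(path: Union[str, Path]) -> list[tuple[int, int]]:
    events = []
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if not parts or not parts[0] or not parts[0].lstrip("-").isdigit():
                continue
            events.append((int(parts[0]), int(parts[1]) if len(parts) > 1 else 1))
    return events


def read_recording(
    path: Union[str, Path], events_path: Optional[Union[str, Path]] = None
) -> MultichannelRecording:
    """Read an EDF recording and attach events from a sidecar file."""
    rec = read_edf(path)
    if events_path is not None:
        events = read_events(events_path)
        offenders = [s for s, _ in events if not 0 <= s < rec.n_samples]
        if offenders:
            raise ValueError(
                f"event sample(s) outside [0, {rec.n_samples}): {offenders}"
            )
        rec.events = events
    return rec


def save_model(model: SassModel, path: Union[str, Path]) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("W", data=model.W)
        fh.create_dataset("lambdas", data=model.lambdas)
        if model.P is not None:
            fh.create_dataset("P", data=model.P)
        if model.selection_curve is not None:
            fh.create_dataset("selection_curve", data=model.selection_curve)
        fh.attrs["band"] = list(model.band)
        fh.attrs["channel_labels"] = [lb.encode() for lb in model.channel_labels]
        if model.k_rejected is not None:
            fh.attrs["k_rejected"] = model.k_rejected


def load_model(path: Union[str, Path]) -> SassModel:
    with h5py.File(path, "r") as fh:
        labels = tuple(
            lb.decode() if isinstance(lb, bytes) else str(lb)
            for lb in fh.attrs["channel_labels"]
        )
        return SassModel(
            W=fh["W"][()],
            lambdas=fh["lambdas"][()],
            band=tuple(float(b) for b in fh.attrs["band"]),
            channel_labels=labels,
            k_rejected=int(fh.attrs["k_rejected"]) if "k_rejected" in fh.attrs else None,
            P=fh["P"][()] if "P" in fh else None,
            selection_curve=(
                fh["selection_curve"][()] if "selection_curve" in fh else None
            ),
        )


def save_ground_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    """Persist the small (non-waveform) part of a GroundTruth as JSON."""
    payload = {
        "ssvep_topography": truth.ssvep_topography.tolist(),
        "artifact_topographies": {
            str(h): v.tolist() for h, v in truth.artifact_topographies.items()
        },
        "true_trial_amplitudes": {
            c: v.tolist() for c, v in truth.true_trial_amplitudes.items()
        },
        "true_trial_phases": {
            c: v.tolist() for c, v in truth.true_trial_phases.items()
        },
        "onset_samples": {c: v.tolist() for c, v in truth.onset_samples.items()},
        "artifact_scale": truth.artifact_scale,
        "config": dataclasses.asdict(truth.config) if truth.config else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path: Union[str, Path]) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    cfg = payload.get("config")
    if cfg is not None:
        for key in ("iti_range", "nonlinearity_coeffs", "bad_power_channels",
                    "saturated_channels"):
            if key in cfg and cfg[key] is not None:
                cfg[key] = tuple(cfg[key])
        cfg = SessionConfig(**cfg)
    return GroundTruth(
        ssvep_topography=np.array(payload["ssvep_topography"]),
        artifact_topographies={
            int(h): np.array(v)
            for h, v in payload["artifact_topographies"].items()
        },
        true_trial_amplitudes={
            c: np.array(v) for c, v in payload["true_trial_amplitudes"].items()
        },
        true_trial_phases={
            c: np.array(v) for c, v in payload["true_trial_phases"].items()
        },
        onset_samples={
            c: np.array(v, dtype=int) for c, v in payload["onset_samples"].items()
        },
        ssvep_waveforms={},
        artifact=None,
        artifact_scale=float(payload["artifact_scale"]),
        config=cfg,
    )


def write_spectrum_tsv(spectrum, labels: Sequence[str],
                       path: Union[str, Path]) -> None:
    rows = []
    for i, lb in enumerate(labels):
        rows.append(pd.DataFrame({
            "freq_hz": spectrum.freqs, "channel": lb, "psd": spectrum.psd[i]
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
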