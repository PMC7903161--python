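"""End-to-end pipeline: QC -> filter -> fit -> apply -> metrics -> stats."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import core, preprocess, ssvep, stats
from .layout import OCCIPITAL_LABELS
from .recording import MultichannelRecording

CONDITIONS = ("no_stim", "stim_raw", "stim_sass")


@dataclass
class PipelineConfig:
    band: tuple[float, float] = (9.0, 11.0)
    flicker_freq: float = 10.0
    trial_duration: float = 2.0
    harmonics: tuple[int, ...] = (1,)
    occipital_labels: tuple[str, ...] = OCCIPITAL_LABELS
    nfft: int = 2048
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    k: Optional[int] = None
    paths: dict = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("band", "harmonics", "occipital_labels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def default_comparisons(trials: dict) -> dict:
    """The three amplitude and three phase comparisons between conditions.

    Directions follow the stated hypotheses: raw-stimulation amplitudes are
    larger than stimulation-free ones; cleaned amplitudes are smaller than
    raw ones; cleaned vs stimulation-free is two-sided (residual artifact).
    """
    amp = {c: trials[c].amplitude for c in CONDITIONS}
    ph = {c: trials[c].phase_diff[trials[c].valid] for c in CONDITIONS}
    # stim_raw and stim_sass share trials: pair them on jointly valid trials
    both = trials["stim_raw"].valid & trials["stim_sass"].valid
    out = {
        "amplitude": {
            "no_stim_vs_stim_raw": stats.t_test(
                amp["stim_raw"], amp["no_stim"], "independent", "greater"
            ),
            "stim_raw_vs_stim_sass": stats.t_test(
                amp["stim_sass"], amp["stim_raw"], "dependent", "less"
            ),
            "no_stim_vs_stim_sass": stats.t_test(
                amp["no_stim"], amp["stim_sass"], "independent", "two-sided"
            ),
        },
        "phase": {
            "no_stim_vs_stim_raw": stats.wallraff_test(
                ph["no_stim"], ph["stim_raw"], "independent"
            ),
            "stim_raw_vs_stim_sass": stats.wallraff_test(
                trials["stim_raw"].phase_diff[both],
                trials["stim_sass"].phase_diff[both],
                "dependent",
            ),
            "no_stim_vs_stim_sass": stats.wallraff_test(
                ph["no_stim"], ph["stim_sass"], "independent"
            ),
        },
    }
    return out


def run_pipeline(
    rec_stim: MultichannelRecording,
    rec_nostim: MultichannelRecording,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Execute the full analysis on an in-memory recording pair.

    Returns a results bundle with the fitted model, per-condition trial
    tables and PLVs, the six standard statistical comparisons, and a
    structured log (one record per stage).
    """
    cfg = config or PipelineConfig()
    log: list[dict] = []

    def stage(name: str, **info) -> None:
        log.append({"stage": name, "seed": cfg.seed, **info})

    # 1. channel quality control (mask from the no-stim condition, applied
    #    to both)
    bad = preprocess.exclude_bad_channels(rec_nostim)
    keep = [lb for lb in rec_nostim.channel_labels if lb not in bad]
    nostim = rec_nostim.pick(keep)
    stim = rec_stim.pick(keep)
    stage("qc", bad_channels=sorted(bad), n_kept=len(keep))

    # 2. narrowband filtering of the full-length recordings
    kernel = preprocess.design_fir(preprocess.FilterSpec(*cfg.band), nostim.fs)
    nostim_f = preprocess.filter_recording(nostim, kernel)
    stim_f = preprocess.filter_recording(stim, kernel)
    stage("filter", band=list(cfg.band), n_taps=int(kernel.size),
          hash_nostim=_digest(nostim_f.data), hash_stim=_digest(stim_f.data))

    # 3-4. covariances, joint diagonalization, component count, projection
    model = core.fit_sass(stim_f, nostim_f, cfg.band, k=cfg.k, prefiltered=True)
    stage("fit", k=int(model.k_rejected),
          lambdas_top=[float(v) for v in model.lambdas[:5]],
          selection_curve=[float(v) for v in model.selection_curve]
          if model.selection_curve is not None else None)

    # 5. apply the projection to the narrowband data for SSVEP metrics
    cleaned_f = core.apply_projection(model, stim_f)
    stage("apply", hash_cleaned=_digest(cleaned_f.data))

    # 6. Hilbert metrics on the virtual occipital channel, full length first
    sources = {"no_stim": nostim_f, "stim_raw": stim_f, "stim_sass": cleaned_f}
    trials, plv = {}, {}
    for cond, rec in sources.items():
        virt = preprocess.virtual_occipital(rec, cfg.occipital_labels)
        onsets = [s for s, _ in rec.events]
        table = ssvep.trial_table(
            virt, onsets, rec.fs, cfg.flicker_freq, cfg.trial_duration,
            condition=cond,
        )
        trials[cond] = table
        plv[cond] = ssvep.phase_locking_value(table.phase_diff[table.valid])
    stage("metrics", plv={c: plv[c].plv for c in plv})

    # 7. the six standard comparisons
    comparisons = default_comparisons(trials)
    stage("stats", p_values={
        f"{family}.{name}": res.p_value
        for family, tests in comparisons.items() for name, res in tests.items()
    })

    return {
        "config": cfg,
        "model": model,
        "bad_channels": sorted(bad),
        "trials": trials,
        "plv": plv,
        "comparisons": comparisons,
        "log": log,
    }


def comparisons_to_json(comparisons: dict) -> dict:
    return {
        family: {
            name: {
                "statistic": res.statistic,
                "p_value": res.p_value,
                "sidedness": res.sidedness,
                "pairing": res.pairing,
                "n": list(res.n),
                "method": res.method,
            }
            for name, res in tests.items()
        }
        for family, tests in comparisons.items()
    }
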