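# sass-eeg

Suppression of amplitude-modulated transcranial alternating current
stimulation (AM-tACS) artifacts in concurrent EEG, via **stimulation
artifact source separation (SASS)**: a spatial filter built from the joint
diagonalization of narrowband sensor covariance matrices recorded during
(`A`) and in absence of (`B`) stimulation. Components whose power ratio
`lambda_i = w_i' A w_i / w_i' B w_i` is largest are attributed to the
artifact and removed by the projection `P = pinv(W) S W`; the rejection
count is chosen automatically by minimizing the mean squared per-channel
band-power mismatch between cleaned during-stimulation data and
stimulation-free data.

The package also ships the full validation tool chain: a synthetic
concurrent EEG / AM-tACS session generator with known ground truth, channel
quality control and zero-phase FIR filtering, single-trial SSVEP
amplitude/phase extraction (Hilbert transform, phase-locking value), Welch
and multitaper spectra, a heartbeat-locked artifact-modulation permutation
test, and the inferential statistics used to validate artifact removal
(t-tests, Wallraff circular dispersion tests, TFCE spatial cluster
permutation, power analysis).

## Layout

| module | contents |
| --- | --- |
| `sass.synth` | synthetic session generator (SSVEP + transduced AM artifact + 1/f noise) |
| `sass.preprocess` | bad-channel exclusion, FIR design/zero-phase filtering, epoching, occipital virtual channel |
| `sass.core` | covariances, joint diagonalization, component selection, projection, per-harmonic fits, SSP baseline |
| `sass.ssvep` | analytic signal, per-trial amplitude/phase, PLV, evoked responses |
| `sass.spectral` | Welch / DPSS multitaper PSD, heartbeat modulation permutation test |
| `sass.stats` | t-tests, Wallraff tests, TFCE cluster permutation, power analysis, group summaries |
| `sass.io` | EDF read/write (16-bit), event tables, HDF5 model persistence, ground-truth JSON |
| `sass.pipeline` / `sass.cli` | end-to-end pipeline and the `sass` command-line tool |

## CLI

```sh
# simulate a stimulation-free / during-stimulation session pair
sass simulate --out-dir session/ --seed 0

# fit SASS (both recordings are required; models are never transferred)
sass fit --stim session/stim.edf --nostim session/no_stim.edf \
         --band 9 11 --model model.h5

# apply to broadband or narrowband data
sass apply --model model.h5 --in session/stim.edf --out cleaned.edf

# single-trial amplitude/phase metrics and statistics
sass evaluate --cleaned cleaned.edf --cleaned-events session/stim_events.tsv \
              --nostim session/no_stim.edf \
              --nostim-events session/no_stim_events.tsv --out metrics.tsv
sass stats --metrics metrics.tsv --out stats.json

# spectra and heartbeat-modulation analysis
sass spectra --in cleaned.edf --method welch --out psd.tsv
sass heartbeat --in session/stim.edf --rpeaks rpeaks.txt --channel O2 \
               --nperm 1000 --seed 0 --out heartbeat.json

# or everything at once
sass run --stim session/stim.edf --stim-events session/stim_events.tsv \
         --nostim session/no_stim.edf \
         --nostim-events session/no_stim_events.tsv --out-dir results/
```

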