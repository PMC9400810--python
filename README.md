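# cardioeeg

Heart–brain coupling analysis for simultaneous EEG+ECG recordings: HRV metric
extraction, EEG band-power mapping on a 10/20 montage, heartbeat-evoked
potentials (HEP), and a cross-modal correlation/regression battery — validated
end-to-end against a synthetic cohort generator with known coupling structure.

## What it does

| Module | Role |
| --- | --- |
| `cardioeeg.synthetic` | Two-group EEG+ECG cohort generator: a latent per-subject "vagal tone" scalar drives both RR high-frequency modulation depth and per-band EEG power (configurable sign/strength per group), plus an injected R-locked evoked component and cardiac-field bleed |
| `cardioeeg.rpeak` | Pan–Tompkins-style R-peak detection (polarity invariant) and NN-interval derivation with artifact exclusion |
| `cardioeeg.hrv` | SDNN, RMSSD, SD1 (Poincaré) and HF power (0.15–0.40 Hz) of the 4 Hz spline-resampled tachogram |
| `cardioeeg.eeg_power` | Butterworth band-pass + 50 Hz notch + linked-mastoid (or common-average) re-referencing, Welch band power (Hamming, 4 s, 0 % overlap) per δ/θ/α1/α2/β band and (ROI, hemisphere), alpha-peak frequency |
| `cardioeeg.hep` | R-locked epoching (−200…+600 ms, 15 Hz low-pass), trial averaging, per-channel group-difference windows (sample-wise ANOVA, Bonferroni, ≥20 ms windows inside the 350–600 ms TOI) |
| `cardioeeg.coupling` | Spearman correlograms (exact permutation p for n ≤ 9), \|ρ\|≥0.5 ∧ p<0.05 report filter, group one-way ANOVA with Bonferroni, exhaustive best-subset OLS over F/C/P/T/O with adjusted-R² selection, Pearson residuals and Shapiro–Wilk diagnostics |
| `cardioeeg.pipeline` / `cardioeeg.cli` | End-to-end orchestration, EDF/CSV I/O, YAML config, deterministic artifact writing |
| `cardioeeg.edf` | Minimal plain-EDF reader/writer (16-bit, 1 s records) |

## CLI

```bash
# generate a synthetic cohort (11 "RE-like" + 7 "control-like", 10 min @ 256 Hz)
cardioeeg simulate --out data/ --seed 1

# per-recording stages
cardioeeg hrv data/sub-01.edf --rr-out rr.csv
cardioeeg bandpower data/sub-01.edf --out bp.csv
cardioeeg hep data/sub-01.edf --out hep.csv

# coupling statistics from saved tables
cardioeeg couple --powers out/band_power.csv --hrv out/hrv.csv --out coupled/

# full pipeline (synthetic mode by default; see RunConfig for real-data mode)
cardioeeg run-all --out out/ --seed 1
```

`run-all` writes `hrv.csv`, `band_power.csv`, `correlogram.csv`,
`correlations_reported.csv`, `regression.csv`, `group_anova.json`,
`hep_waveforms.csv`, `hep_windows.json` and `report.json`, and is
byte-deterministic for a fixed seed.

Real recordings are consumed as EDF or plain CSV (one column per channel,
header row); T7/T8/P7/P8 are accepted as synonyms of T3/T4/T5/T6.

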