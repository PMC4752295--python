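# ecgstab

Early-warning analytics for hemodynamic instability from single-lead ECG.
From a raw 500 Hz waveform, the pipeline detects and delineates P-QRS-T
fiducials, extracts four feature families — peak-morphology ratios and
interactions, taut-string variability indices of the R-R series, 5-level
dual-tree complex wavelet statistics, and the traditional time/frequency
HRV baseline — then applies two-stage feature selection (mean-correlation
redundancy removal + cross-validated forward stepwise selection) and
evaluates a linear SVM under nested subject-wise 10-fold cross-validation.

Because no public dataset of staged central-hypovolemia recordings exists,
the package ships a first-class synthetic cohort generator
(`ecgstab.synthetic`) producing multi-stage records with known ground
truth: LF/HF heart-rate oscillations, per-subject beat morphology,
respiratory R-amplitude modulation, baseline wander, noise at a
configurable SNR, and a monotone severity effect across stages.

## Command line

```bash
# synthetic cohort as two-column CSV records + JSON truth sidecars
ecgstab simulate --n-subjects 10 --seed 1 --out data/

# records -> labeled windows x features table
ecgstab extract --input data/ --out table.csv --beats-per-window 120

# two-stage feature selection (Table-style report with t-ratios and VIFs)
ecgstab select --table table.csv --k 10 --seed 1 --out selection.csv

# nested-CV linear SVM on a feature group
ecgstab train --table table.csv --features typical --seed 1

# everything in one reproducible run (JSON config, hashed outputs)
ecgstab run --seed 1 --out runs/demo
ecgstab report --run-dir runs/demo
```

`ecgstab run` writes `feature_table.csv`, `feature_manifest.csv`,
`selection_report.csv`, `cv_presented.csv`, `cv_typical_hrv.csv`,
`severity_regression.csv` and `provenance.json`; every CSV carries the
configuration hash in its first line.

## Library layout

| module | contents |
| --- | --- |
| `ecgstab.synthetic` | cohort / record / R-R series simulation, CSV+JSON I/O |
| `ecgstab.preprocess` | tumbling beat-count windows, degree-6 baseline removal, Savitzky-Golay |
| `ecgstab.peaks` | level-10 db4 low-frequency filter, adaptive R detector, P/Q/S/T delineation, missing-peak imputation, amplitude normalization |
| `ecgstab.features.morphology` | interval-ratio, amplitude difference/ratio/interaction, HRV-spectral and ECG-derived-respiration features |
| `ecgstab.features.tautstring` | linear-time tube taut-string solver, epsilon-sweep features, `ts32_v` variability index |
| `ecgstab.features.dtcwt` | 5-level dual-tree complex wavelet transform (exact reconstruction, near-analytic subbands) and statistics |
| `ecgstab.features.hrv` | SDNN/SDSD/RMSSD/pNN50, periodogram PSD, LF/HF powers, moments |
| `ecgstab.selection` | mean-correlation redundancy removal, forward stepwise selection, VIF diagnostics |
| `ecgstab.model` | labeling/severity scheme, nested-CV linear SVM, Mann-Whitney comparisons, window-size sweep, severity regression |
| `ecgstab.pipeline` / `ecgstab.cli` | orchestration, provenance, CLI |

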