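# pdmotion

Smartphone accelerometry analytics for Parkinson's disease (PD) motor
assessment. From tri-axial accelerometer recordings of three brief motor
tasks — 20 s of hand resting tremor, a 25-foot walk, and a 360° turn, all
sampled at 100 Hz by a strap-mounted phone — the package:

* conditions each signal (Euclidean magnitude → zero-phase Butterworth
  low-pass → zero-baseline calibration);
* extracts the tremor feature set `PF4_6`, `%PF4_6`, `PR`, `PF0_20`,
  `PEAK_POWER`, `AVG_ACC` from the Welch power spectral density
  (parkinsonian rest tremor concentrates at 4–6 Hz), and the gait/turn
  feature set `CT`, `SL`, `SP`, `AVG_ACC`, `NUM_TURN`, `TURN_SP` from
  stride-event segmentation, including freezing-of-gait episode detection;
* detects resting tremor (UPDRS item ≥ 1) and gait difficulty (UPDRS
  item ≥ 2) with linear-kernel SVM classifiers, and estimates Hoehn & Yahr
  stage and UPDRS item severities with Lasso regressions;
* evaluates everything with stratified 5-fold cross-validation, reporting
  pooled sensitivity/specificity/accuracy and Pearson correlations.

A synthetic-signal generator reproduces the published signal morphologies
(graded tremor amplitude and intermittency, quasi-periodic stride trains,
freezing gaps, turning step sequences) and a 40-subject labelled cohort
with exact ground truth, so the whole pipeline is testable without patient
data. Intended users: researchers in digital biomarkers and movement
disorders who need a transparent, reproducible reference implementation of
this class of pipeline.

## Worked example

```python
from pdmotion import TremorSimSpec, simulate_tremor, extract_tremor_features

rec, truth = simulate_tremor(TremorSimSpec(severity=2), seed=7)
f = extract_tremor_features(rec)
print(f"true mean |a| = {truth.mean_abs_acc:.3f} m/s^2 at {truth.tremor_freq:.2f} Hz")
for k, v in f.as_dict().items():
    print(f"{k:>10s} = {v:.4g}")
```

prints

```
true mean |a| = 0.850 m/s^2 at 5.25 Hz
     PF4_6 = 1.703
 PCT_PF4_6 = 0.9486
        PR = 65.56
    PF0_20 = 1.796
PEAK_POWER = 4.257
   AVG_ACC = 0.8765
```

A moderate (UPDRS 2) tremor is intermittent: in-burst amplitude 1.7 m/s² at
50 % duty gives a full-record mean near 0.85 m/s², which `AVG_ACC`
recovers. 95 % of the signal power lies in the 4–6 Hz tremor band
(`PCT_PF4_6`), the tremor-to-drift power ratio `PR` is far above 1, and the
density peaks at 4.26 (m/s²)²/Hz at the generated 5.25 Hz.

The full desk-scale pipeline (simulate cohort → extract features → train →
cross-validate) runs from the shell:

```bash
pdmotion run --seed 42 --out-dir out/
```

```
tremor_present: sensitivity=1.00 specificity=1.00 accuracy=1.00
gait_difficulty: sensitivity=0.95 specificity=1.00 accuracy=0.97
hoehn_yahr: pearson_r=0.90
tremor_updrs: pearson_r=0.94
gait_updrs: pearson_r=0.82
```

On the synthetic cohort the severity archetypes are well separated, so the
detectors operate near ceiling; the regressions are bounded by the stochastic coupling
between disease stage and the per-task severity items. `out/` receives
`features.csv`, `labels.csv`, `config.json` and `report.json` (per-fold and
pooled metrics). Other subcommands: `pdmotion simulate cohort`,
`pdmotion extract`, `pdmotion train`, `pdmotion evaluate`.

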