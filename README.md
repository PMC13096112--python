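# stimvision

Objective, within-session ranking of deep-brain-stimulation (DBS) programs
from smartphone-derived hand kinematics in Parkinson's disease.

DBS programming is usually guided by observer-rated scales and trial-and-error
parameter adjustment. This package implements the analysis layer that turns a
one-dimensional **hand-aperture signal** — the normalized distance between the
third-digit tip and the wrist while the patient performs repetitive hand
opening–closing (MDS-UPDRS item 3.5), sampled at 60 Hz from smartphone video —
into an objective, patient-specific ranking of the stimulation programs tested
in a session, plus the cohort-level statistics and kinematic-domain analyses
built on top of it. It is written for movement-disorder researchers and
neurology groups working on data-driven DBS programming; pose estimation and
video processing are upstream of this package, which starts at the aperture
signal (or directly at a feature table).

## The model

For each patient-hand session with a stimulation-off baseline and candidate
programs p = 1…P:

1. **Features.** 23 kinematic parameters x_j are extracted per condition,
   covering amplitude, speed/vigor, temporal rhythm, variability, and
   within-sequence decrement (e.g. mean RMS velocity, closing speed,
   frequency, amplitude-decay slope). Each feature carries an orientation
   flag (higher- or lower-is-better).

2. **Improvement matrix.** Oriented percent change vs the patient's own
   off baseline:

   ```
   I(p, j) = s_j · 100 · (x_j(p) − x_j(off)) / |x_j(off)|,   s_j = ±1
   ```

   so positive always means improvement. Near-zero baselines are masked,
   not divided through.

3. **Responsiveness weights.** r_j = SD_p I(p, j), the across-program
   standard deviation of each feature's improvement — features that
   discriminate between programs in *this* patient get weight. Weights are
   normalized, optionally shrunk toward uniform over the responsive set:

   ```
   w_j(λ) = (1 − λ) · r_j / Σ r  +  λ / |{j : r_j > 0}| ,   λ ∈ [0, 1]
   ```

4. **DWIS.** The Dynamically Weighted Improvement Score of a program is the
   weighted sum DWIS(p) = Σ_j w_j · I(p, j); the off condition is anchored at
   0, programs are ranked by DWIS, and a λ-grid sensitivity report flags
   whether the top choice is stable over λ ∈ [0, 0.45] (λ = 0.1 is the
   default for the main analysis).

Cohort-level layers: one-sample Wilcoxon signed-rank tests of median
improvement > 0 per feature with Benjamini–Hochberg FDR across the 23 tests
and bootstrap CIs for medians; DWIS polarity and top-vs-second separation
summaries; a linear mixed-effects model (random intercept per patient-hand)
relating ΔDWIS to clinician-rated MDS-UPDRS item 3.5 change; and sparse PCA
(3 components, ℓ1 penalty 1.0) that distills the patients × features
improvement matrix into kinematic domains, compared across therapy cohorts
with Tucker's congruence coefficient Φ and a feature-permutation test of
global structural similarity.

A synthetic-cohort module generates quasi-periodic aperture traces, whole
sessions with a planted best program, improvement matrices with planted
sparse domain structure, and concordance datasets with a planted slope, so
the entire pipeline is testable end to end without recorded data.

## Worked example

```python
import numpy as np
from stimvision import (
    batch_extract, build_improvement_matrix, compute_dwis, default_session_spec,
    dynamic_weights, generate_patient_session, lambda_sensitivity, responsiveness,
)

traces, planted = generate_patient_session(default_session_spec(seed=42, n_programs=6))
table, _ = batch_extract(traces)
matrix = build_improvement_matrix(table.drop(columns=["patient_id", "hand"]), "OFF")
weights = dynamic_weights(responsiveness(matrix), lam=0.1,
                          feature_names=matrix.feature_names)
ranking = compute_dwis(matrix, weights)
report = lambda_sensitivity(matrix)

print("planted best:", planted)
for i in ranking.order:
    print(f"  rank {ranking.ranks[i]}: {ranking.program_labels[i]:>5s}"
          f"  dwis = {ranking.dwis[i]:+7.2f}")
print(f"delta_top2 = {ranking.delta_top2:.2f}, stable across lambda grid: {report.stable}")
```

prints

```
planted best: Pr01
  rank 1:  Pr01  dwis =  +53.80
  rank 2:  Pr05  dwis =  +19.54
  rank 3:  Pr03  dwis =  +16.68
  rank 4:  Pr02  dwis =  +10.22
  rank 5:  Pr06  dwis =   +5.08
  rank 6:  Pr04  dwis =   +1.93
  rank 7:   OFF  dwis =   +0.00
delta_top2 = 34.27, stable across lambda grid: True
```

The session seeded at 42 plants `Pr01` as the dominant program (+40%
amplitude, +30% frequency, decrement and timing jitter halved); the pipeline
recovers it as rank 1 with DWIS +53.8 weighted-percent, separated from the
runner-up by 34.3, and the choice does not change anywhere on the shrinkage
grid. The off baseline sits at exactly zero by construction.

The same pipeline is available from the shell:

```
stimvision simulate session --seed 42 --n-programs 6 --out traces/
stimvision extract --traces traces/ --out features.csv
stimvision score --features features.csv --baseline OFF --lambda 0.1 --out ranking.json
stimvision report --features features.csv --out reports/
```

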