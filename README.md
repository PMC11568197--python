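# spafnirs

Analysis pipeline for **systemic-physiology-augmented functional
near-infrared spectroscopy (SPA-fNIRS)** recordings of preterm neonates
during live music-therapy sessions, for researchers studying evoked
cerebral-haemodynamic responses in the NICU.

During a 55-minute, 9-interval bedside protocol (baseline, therapeutic
touch, two 10-minute humming/singing intervals, holding and rest periods),
cerebral tissue oxygen saturation (StO₂, %) is recorded at 1 Hz over the
left auditory cortex (AC) and right prefrontal cortex (PFC), alongside
peripheral arterial saturation (SpO₂) and pulse rate (PR) at 0.25 Hz and a
3-axis accelerometer on the sensor. The package implements the full chain:

1. **Preprocessing** — zero-phase FIR antialias downsampling of StO₂ to
   0.25 Hz; Savitzky–Golay smoothing (2nd degree, ~32 s window) of SpO₂ and
   PR; motion-artifact removal by thresholding the moving standard
   deviation (50 s window) of the summed acceleration, deleting flagged
   epochs from every physiological channel.
2. **Derived measures** — fractional tissue oxygen extraction
   FTOE = (SpO₂ − StO₂)/SpO₂; per-interval medians; normalization of each
   signal to its first-touch (interval 2, 5–10 min) median; evoked changes
   ΔX = median(interval 3) − median(interval 2); subgroup block averages
   (pointwise median and 25th/75th percentiles).
3. **Response classification** — per subject, a Wilcoxon rank-sum test of
   interval-3 vs interval-2 StO₂(AC) samples; the sign of the median
   difference assigns subgroup 1 (increase) or subgroup 2 (decrease), with
   the test's significance recorded separately.
4. **Group statistics** — Wilcoxon signed-rank tests with matched-pairs
   rank-biserial effect sizes r_rb = (T⁺ − T⁻)/(T⁺ + T⁻); Welch's t-test
   between subgroups; a Mann–Whitney demographic battery with
   r_rb = 2U/(n₁n₂) − 1; the sex-by-subgroup 2×2 suite (Pearson χ² without
   continuity correction, log odds ratio with Wald 95% CI, Kendall τ-b from
   its 2×2 closed form); Spearman covariate screening (e.g. haematocrit vs
   ΔStO₂).
5. **Coupling models** — per site and subgroup, a Gaussian identity-link GAM
   ΔStO₂ = β₀ + f(ΔSpO₂, ΔPR) + ε with f a penalized tensor-product
   B-spline surface, smoothing parameters by generalized cross-validation;
   reported via explained deviance, an approximate term test and
   monotonicity/curvature classification of the partial effects.
6. **Synthetic cohorts** — a seedable generator that plants the study
   structure (two response subgroups ≈ +3.2%/−1.2% StO₂, habituated second
   responses, sex-imbalanced subgroups, haematocrit-linked amplitudes, 1/f
   noise, motion bursts) so the whole pipeline is testable without any
   clinical data.

## Worked example

```sh
spafnirs synth-cohort --out demo/data --seed 7
spafnirs run-all --input-dir demo/data --out demo/bundle --seed 7
```

prints

```
wrote 17 sessions to demo/data
subgroups: n1=9 n2=8 unassigned=0 significant=17
bundle written to demo/bundle
```

meaning that of the 17 synthetic neonates, 9 showed a StO₂ increase during
the first singing interval (subgroup 1), 8 a decrease (subgroup 2), and all
17 individual changes were significant at α = 0.05. `demo/bundle/report.md`
summarises the run; for this seed it includes

```
counts (sg1 F/M, sg2 F/M) = (7, 2, 3, 5); chi2 = 2.837 (df=1, p = 0.092);
log OR = -1.764 [-3.889, 0.362]; tau-b = -0.408
```

— the sex-by-subgroup association of this particular cohort draw. The same
computations from the library:

```python
from spafnirs import contingency_suite
res = contingency_suite(8, 2, 2, 5)   # subgroup 1: 8F/2M, subgroup 2: 2F/5M
print(res.chi2, res.log_or, res.tau_b)
# 4.496326530612244 -2.3025850929940455 -0.5142857142857142
```

The bundle directory holds tidy TSVs (quality report, assignments, deltas,
subgroup statistics, demographic battery, block-average curves, fitted GAM
surfaces) plus `results.json` with the contingency suite, coupling report
and a run manifest (config hash + seed) that makes runs reproducible.

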