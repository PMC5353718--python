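# Methods

## Task and signal model

The measurement block is fixed: 10 s pre-task rest, 60 s letter
verbal-fluency task, 55 s post-task rest, sampled at 0.1 s (configurable).
Recordings are 52-channel oxy-Hb concentration-change series (arbitrary
units, mM·mm convention); the analyzed region of interest is the 11-channel
frontal cluster (channels 25–28, 36–38, 46–49, 1-based).  Deoxy-Hb can be
carried alongside but is never analyzed.

The synthetic hemodynamic response is a piecewise kernel relative to task
onset: zero until the onset latency L, a linear ramp to amplitude A over
15 s, a plateau until the latency-shifted task end, then exponential decay
with a 15 s time constant.  This shape was chosen because it reproduces the
canonical rise–plateau–return morphology of frontal verbal-fluency
responses while having a closed-form task-window area,
A·(52.5 − L) for L ≤ 45 s, which serves as the oracle for the
feature-extraction tests.  A latency shift is an exact time translation, so
centroid shift equivariance can be asserted to machine precision.

## Synthetic cohort generator (`synthgen`)

Defaults emulate the study conditions end to end:

| parameter | default | why |
|---|---|---|
| group sizes | SCZ 45, MDD 26, BIP 22, HC 51 | the cohort structure all designs derive from |
| FH+ fraction (any psychiatric) | 17/45, 10/26, 10/22, HC 0 | pooled FH+ 37 vs FH− 56; keeps every patient classifiable so the pooled model has denominator df 138 |
| FH nesting | P(major\|any)=0.65, P(same\|major)=0.5 | three nested indicators: same disorder ⇒ major psychiatric ⇒ any psychiatric |
| fh_unknown_rate | 0.0 | unknown histories are a patient-only phenomenon; raised in tests to exercise exclusion |
| amplitude means | per diagnosis-by-FH cell | chosen so cell mean integrals sit at 85 + d·30 (arbitrary units) with d the cell's standardized offset from controls (SCZ+ −1.21, SCZ− −0.48, MDD+ −1.21, MDD− −0.80, BIP+ −0.74, BIP− −1.34), compensating each cell's latency-shortened kernel area |
| amplitude_sd | 0.62 | ≈ 30 / mean task-window kernel area (~48): within-group integral SD ≈ 30, placing the patient/control boundary near the integral threshold 73 |
| latency means (s) | HC 6, SCZ− 12, SCZ+ 15.5, MDD± 12, BIP− 14, BIP+ 18 | put psychosis-spectrum centroids near/above the 54 s threshold and controls/MDD below, with FH+ cells latest |
| latency_sd_s | 4 | within-group timing variability; without it every subject in a cell would share one centroid and threshold classification would be degenerate |
| noise_sd | 0.3 | sensor noise per sample; at 11-channel averaging it contributes ~1 unit to the integral SD, realistically negligible against between-subject variation |
| artifact_channel_rate | 0.02 | occasional corrupted channels; corruption = step of ≥10× noise SD plus three 20× spikes, chosen so a jump detector can find them |

Demographics (age, education, premorbid IQ, task performance, CPZ-equivalent
dose, onset age, symptom scales) are truncated normals with group-specific
means/SDs and exact gender/handedness count ratios; they exist only as
covariates and metadata, so their exact distributional shape is immaterial.
Counts are exact by construction: FH+ per diagnosis is round(fraction·n),
and one recording is generated per subject from a single integer seed
(bit-reproducible).

What the generator does *not* emulate: optical physics (wavelengths and the
modified Beer–Lambert step are metadata only), spatial correlation between
channels, physiological confounds (Mayer waves, respiration, scalp flow),
motion artifacts beyond step/spike corruption, and any dependence of
features on medication or symptoms.  Passing tests therefore demonstrate
correctness of the estimators and decision rules under a clean additive
model, not robustness to real-world fNIRS confounds.

## Feature extraction (`waveform`)

**Channel QC.**  A cluster channel is rejected when its largest
sample-to-sample jump exceeds k (default 10) times the MAD of its first
differences *and* half its robust peak-to-peak range (0.5–99.5 percentile),
or when it is constant.  With Gaussian noise the difference MAD is ~0.95 σ,
so k = 10 puts the threshold near 9.5 σ: the generator's ≥10 σ steps and
20 σ spikes are caught while the largest clean-noise jump (~6–7 σ at 1250
samples) stays clear.  The range floor exists for noise-free channels,
whose difference MAD vanishes and would otherwise flag every smooth signal.
Subjects with fewer than 6 of 11 surviving channels are excluded
(`insufficient_channels`), with features absent.

**Baseline.**  Default mode `prepost` subtracts, per channel, the straight
line through the pre-task mean (first 10 s) and the late post-task mean
(final 5 s) — the standard drift correction for this block design; a pure
linear drift maps exactly to zero.  Mode `pre` subtracts the pre-task mean
only; it is the mode under which a noise-free kernel subject's integral
equals A·(52.5 − L) to ≤1e−9 relative error (the prepost line is nonzero
because the exponential tail has not fully decayed at 110–115 s).

**Integral.**  Trapezoidal rule over [onset, offset], signed; no smoothing
by default (an optional moving-average width is exposed).

**Centroid.**  Computed on the positive part of the ROI signal over
[task onset, end of measurement], reported in seconds after task onset —
consistent with the 54 s decision threshold lying inside the 60 s task.
Negative excursions are excluded from both numerator and denominator.  The
half-area crossing is located by inverting the trapezoid rule inside the
bracketing sample panel (the cumulative area is quadratic there; a linear
fallback handles flat panels), with the earliest crossing taken on exact
ties.  This inversion is exact for piecewise-linear signals, which is what
lets the test suite demand 1e−6 agreement with a dense-grid brute-force
oracle.  A signal with no positive area yields an undefined centroid,
flagged (`undefined_centroid`) without failing QC.

## Group statistics (`cohortstats`)

The omnibus model is OLS with a treatment-coded group factor plus age,
gender (0/1 indicator) and task performance.  The reported F is the
nested-model comparison (full vs covariates-only), which coincides with the
type-III factor F when the grouping is the only categorical term; the
denominator df is N_used − levels − covariates, giving 137 / 138 / 90 for
the 4-group, pooled-FH and single-diagnosis-FH designs at the default
cohort sizes.  Rows failing QC or missing covariates are dropped listwise
per model and counted.  LSD post hocs are unadjusted t tests on
covariate-adjusted mean differences using the omnibus residual variance and
df (no multiplicity correction, by design).  Cohen's d is computed from raw
group values with the pooled-SD formula — not from adjusted means — which
is the convention of the standard effect-size calculators this field uses;
adjusted differences are reported alongside in the post hoc table.
Demographic tests follow variable type (rank tests for continuous, χ²
without continuity correction for categorical), with a Lilliefors-style
normality screen (parameters estimated from the data; a plain fitted-KS
switch is exposed).  Family-history groupings exclude unknown-FH patients
from the model rather than imputing.

Monte-Carlo calibration of the omnibus test uses a projection (QR)
computation of the same nested F across thousands of replicate null
responses; a unit test verifies it equals the `ancova` fit's F on
individual replicates.

## Classification (`classify`)

Thresholds are configuration values defaulting to the given constants
(integral 73, centroid 54 s); no ROC refitting is performed, since the
deriving dataset is external.  Exact ties classify as the clinical case
(patient / psychosis-spectrum) and are logged — determinism plus
auditability.  Undefined centroids classify as `indeterminate` and are
excluded from the psychosis-spectrum numerator only.  Percentage
denominators are QC-passing subjects per group.

## Problem sizes and numerical tolerances

The test suite runs the full default cohort (144 subjects) through the
statistics, and smaller cohorts (20–40 subjects, 0.5 s sampling) through
recording-level Monte Carlo: the generator calibration check uses 120
replicate two-group cohorts compared against the closed-form standardized
gap at 3 Monte-Carlo SEs.  Effect-size recovery uses 2000 replicate normal
draws per contrast; because the plug-in pooled-SD d estimator has known
finite-sample bias E[d̂] = d/J(df), the replicate mean is compared against
that exact expectation (and against d itself at the looser ±0.025).  The
type-I error check runs 5000 null ANCOVAs and requires the rejection rate
in [0.04, 0.06] at α = 0.05.  Oracle comparisons for the features are at
1e−6 relative (brute-force trapezoid and dense-grid half-area scans);
exactness statements (noise-free integral, drift removal) are at 1e−9 to
1e−10.

## Known limitations

- The generator's group effects are configured at the cell level; realized
  whole-cohort effect sizes in any single simulated cohort carry sampling
  error of ~0.2 at these group sizes, and the latency–amplitude coupling
  makes the emulation approximate rather than exactly calibrated.
- "Software filtering" of channels is a simple jump/dead screen; no
  wavelet or regression-based motion correction is attempted.
- The centroid definition uses the positive-area reading of the half-area
  statistic; whether the original convention divides by total |area| is
  ambiguous, and the positive-area interpretation is adopted explicitly.
- Thresholds (73, 54 s) are treated as fixed constants; their external
  validity on synthetic data is structural, not empirical.
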