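# Methods

## The estimation problem

Intravascular filling pressure (left ventricular end-diastolic pressure
or pulmonary capillary wedge pressure, mmHg) is the gold-standard
measure of intravascular volume, obtainable only by cardiac
catheterization. The pipeline estimates it from the fingertip PPG
response to a Valsalva maneuver: strain reduces preload, and the degree
to which the pulse amplitude fails to attenuate by end-strain indexes
volume overload. Two endpoints are modeled: a continuous regression of
filling pressure, and binary classification of volume overload, defined
as pressure strictly above 15 mmHg (10 mmHg as a sensitivity cutoff).

## Synthetic cohort model

No patient-level recordings are publicly available for this problem, so
the package ships a generator whose defaults emulate the published
summary statistics of a cirrhosis catheterization cohort. It is the
substrate for every test.

**Latent pressure.** A two-component truncated-normal mixture:
with probability 0.35 (the overload prevalence) pressure is drawn from
Normal(23.67, 6.00) truncated to > 15 mmHg, otherwise from
Normal(10.59, 3.02) truncated to (0, 15]. Truncation shifts the
realized group means (to ≈ 24.6 and ≈ 10.1 mmHg); the mixture mean,
≈ 15.2 mmHg, matches the published overall summary. Tests therefore
compare group moments against a rejection-sampling oracle rather than
the nominal component means.

**Attenuation map.** The end-strain/rest amplitude ratio is logistic in
pressure, r(P) = r_min + (1 − r_min)·σ((P − P₀)/s), with r_min = 0.4,
midpoint P₀ = 15 mmHg and scale s = 3 mmHg. The clinical literature
reports only the qualitative contrast (strong attenuation at low
pressure, essentially none in overload), not a parametric
dose–response; the logistic form places maximal slope at the clinical
cutoff, so classification is learnable from the waveform but the map
saturates at both extremes. Acceptance therefore rests on parameter
recovery and ordering properties, not on reproducing any patient-level
statistic.

**Waveform synthesis.** Beats follow a renewal schedule at the
subject's heart rate (Normal(72, 9) bpm truncated to 40–140) with 3%
relative interval jitter. Each beat is a stereotyped asymmetric pulse
p(u) = u²(1−u)⁵ (normalized to unit peak; fast systolic upstroke at
phase 2/7 of the beat, slower decay), scaled by a per-beat amplitude:
baseline 1.0 AU × a per-subject lognormal gain (log-SD 0.2) × the strain
envelope × 3% beat-to-beat jitter. The envelope is 1 at rest, declines
linearly to r(P) over the first 4 s of strain and plateaus there —
pulse amplitude settles within a few beats of strain onset, so the
end-strain analysis window sits on the plateau — then ramps back to 1
over the first 5 s of recovery. Additive white noise (SD 0.02 AU) and a
slow sinusoidal baseline drift (0.10 AU at 0.08 Hz, random phase)
complete the trace, sampled at 100 Hz. Three trials per subject follow
the clinical protocol: 30 s rest, 10 s strain at a 25 mmHg mouth-pressure
target, 15 s of recorded recovery, 1 min between trials.
`SimConfig.noiseless()` switches off every nuisance term, giving the
analytic envelope exactly; this is the regime in which feature
extractors are validated against closed forms.

**BNP comparator.** log BNP = 3.4 + 0.126·P + ε, ε ~ Normal(0, 1.6),
censored at an assay ceiling of 5000 pg/ml (which also bounds the
leverage the lognormal tail would exert on a linear fit). The noise SD
is calibrated so a BNP-only regression attains a cross-validated R²
near 0.2 at moderate cohort sizes — BNP must be weakly, but not
uselessly, predictive, matching its clinical behavior.

**Age** is Normal(62.6, 10.4) years truncated to [18, 95]. All
randomness flows from a single seed through per-subject spawned
substreams, so cohorts are bit-reproducible and subject *i* does not
depend on cohort size.

### What the generator does not emulate

Motion artifact, probe repositioning, arrhythmia (excluded from the
clinical protocol), respiratory amplitude modulation beyond a single
drift sinusoid, incomplete or sub-target strains, and any dependence of
pulse morphology (width, reflected wave) on pressure — in the generator
only the amplitude envelope carries information. Passing tests
demonstrate that the pipeline recovers a known encoding from realistic
pulse trains; they cannot certify performance on real patients, where
the pressure–waveform coupling is unknown and noisier. Default-condition
cohorts separate the classes strongly (LDA AUROC near 1 at n = 300);
that reflects the chosen attenuation map, not expected clinical
performance.

## Feature extraction

**Beat detection.** The trace is smoothed with a zero-phase 3rd-order
Butterworth low-pass at 8 Hz, detrended by a 1-s rolling median, and
peaks are picked with prominence ≥ 0.25 × the 5–95% span of the
detrended signal and a 0.33 s refractory period (≤ 180 bpm). Feet are
smoothed-signal minima between consecutive peaks; the first and last
peaks lack a flanking foot and yield no beat. All thresholds are
relative, making detection invariant to amplitude scaling.

**Per-beat metrics** (on the raw samples): amplitude = peak minus foot
level; width = time between the linear-interpolated crossings of
foot + amplitude/2 around the peak; AUC = trapezoidal integral above
foot level across the beat. Beats whose half-height level is never
crossed are dropped and logged, and excluded from window aggregates.

**Windows.** The analysis windows are the terminal 5 s of rest and of
strain ("end rest", "end Valsalva"). The 5 s default targets the
end-strain phase where the physiologic contrast is maximal; the strain
envelope has plateaued there. Aggregates: mean and SD (n−1) of beat
amplitudes, mean width, mean AUC, and RMS power = root-mean-square of
the mean-subtracted raw samples in the window. The signal-RMS reading
of "RMS power" is one of several possible (RMS of beat amplitudes, or
squared RMS); the alternatives are noted but not implemented.

**Ratios** are end-Valsalva ÷ end-rest for mean amplitude, mean AUC and
RMS power, so normal attenuation gives values < 1. Trials failing
detection or windowing are dropped per trial; a subject's features are
the arithmetic means over their valid trials, and subjects with no
valid trial are dropped and logged.

## Candidate pool and selection

Nine waveform bases (window means/SDs/widths plus the three ratios) and
age are expanded with all squares and pairwise products: 10 + 10 + 45 =
65 columns in deterministic order (bases, squares, interactions, each
lexicographic). Forward selection greedily adds the candidate
maximizing the in-sample criterion (OLS R² for regression; refit
accuracy of the chosen classifier for classification), capped at three
terms, ties broken by column order, stopping early if nothing improves.
Selection runs on the full dataset rather than within CV folds — a
deliberate small-cohort concession, mirrored from the clinical
workflow, whose optimism the three-term cap mitigates. The permuted-
target controls in the acceptance checks quantify the residual
optimism: with 65 candidates and n = 300, selection on noise yields
CV R² ≈ 0 and AUROC ≈ 0.5.

The three-term constructions of the published final models (for the
regression and both classification cutoffs) are addressable by name via
`final_model_features`, and the classifier runner accepts either those
fixed terms (`published`) or a fresh search (`search`, the default) —
the source workflow describes both.

## Cross-validated modeling

Regression uses OLS with intercept (statsmodels); exactly collinear
columns (singular value < 1e-10 × largest, intercept included) are
dropped with a warning. CV R² uses seeded shuffled fivefold splits,
refits per training fold, and applies the pooled formula
1 − Σ(yᵢ − ŷᵢ)²/Σ(yᵢ − ȳ)² over concatenated held-out predictions.

Classification uses stratified seeded fivefold CV (nine positives per
26 subjects cannot otherwise populate five folds reliably). Fixed
hyperparameters: KNN k = 5; tree depth ≤ 3; SVM C = 1 with RBF kernel,
bandwidth 1/(p·Var); logistic regression, KNN and SVM standardize
features inside the fold (scaler fit on training rows only); LDA and
the tree operate on raw features. Held-out scores (posterior
probability of overload; signed decision values for the SVM) and
predicted labels are pooled across folds and each metric is computed
once: accuracy, precision (0 when nothing is predicted positive),
recall, specificity, F1 (0 when precision + recall = 0), and AUROC via
the Mann–Whitney U statistic with ties counted one half. Pooling (vs
per-fold averaging) is stable at 26-subject scale and makes the dummy
baseline's values exact: predicting the training-fold majority with a
constant score gives recall 0, precision 0, F1 0, specificity 1 and
AUROC exactly 0.5 whenever the negative class is the majority. The
BNP-only comparator runs through the identical machinery with a single
column; if BNP is constant the regression comparator degrades to an
intercept-only fit rather than erroring.

## Agreement analysis and reporting

Bland–Altman: differences are predicted − actual, limits of agreement
are bias ± 1.96 × SD(differences) (standard normal 95% multiplier), and
a proportional-bias slope (difference regressed on pair mean) is
reported with its p-value. For in-sample OLS predictions with an
intercept the bias is exactly zero — a useful identity test. Both
in-sample and pooled held-out predictions are emitted, labeled, since
either can legitimately populate the plot. The report table carries one
row per case with the selected terms and the metric suite for model,
dummy and BNP arms, re-serialized from the modeling outputs without
recomputation.

## Numerical and design notes

* Waveform files store time to 1e-7 s and samples to 6 significant
  digits; readers enforce uniform spacing to 1e-6 s and reject
  non-finite samples naming the row. Round-trip tolerance is 1e-5 AU.
* Stored overload flags are recomputed from pressure on read; mismatch
  is an error, not a repair.
* The pulse template is smooth and zero-valued at both beat boundaries,
  so zero-noise feet are exact and discretization error in beat metrics
  at 100 Hz is far below the 1% oracle tolerance.
* Degenerate mixture weights (prevalence 0 or 1) are allowed: they give
  exact expectations for distribution-level tests.
* Measurement-noise degradation is asserted as a seed-paired trend
  (metrics centered within replicate, Spearman test across the noise
  grid {0, 0.05, 0.1, 0.2} AU) using the fixed published feature
  constructions: an adaptive forward search routes around corrupted
  features and masks the dose–response that a fixed model shows.
* Problem sizes used by the test suite and acceptance script — 300
  subjects for parameter recovery, 20 replicate cohorts of 200 for the
  BNP comparison, 10,000 covariate-only subjects for distribution
  calibration, 20 × 4 cohorts of 60 for the noise trend — were chosen
  to keep Monte-Carlo error well inside the asserted tolerances.

## Known limitations

The attenuation map, pulse morphology and noise model are modeling
choices constrained only by qualitative physiology; none is identified
by published data. Classification at default conditions is easier than
clinical reality (see above). The >10 mmHg sensitivity cutoff bisects
the non-overloaded component near its mode, so its labels are noisier
by construction. No motion-artifact rejection beyond prominence gating
is implemented, and the package does not read vendor device formats or
EDF/WFDB.
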