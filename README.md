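# ppgvol

Noninvasive estimation of intravascular volume status in cirrhosis from
finger-photoplethysmography (PPG) waveforms recorded during a Valsalva
maneuver.

Patients with decompensated cirrhosis are routinely diuresed against an
intravascular compartment no one can measure without a cardiac
catheterization. Physiology offers a workaround: a Valsalva strain (10 s
of forced expiration against 25 mmHg of mouth pressure) reduces cardiac
preload, and in a normally filled circulation the fingertip pulse
amplitude collapses by end-strain — while in intravascular volume
overload (filling pressure, LVEDP/PCWP, above 15 mmHg) the response is
blunted and the pulse barely changes. `ppgvol` implements that analysis
as a tested pipeline, for physiologists and biomedical-signal
researchers who want to study the approach without access to patient
recordings:

* a **synthetic cohort generator**: three annotated Valsalva trials per
  subject, latent filling pressures drawn from a two-group
  truncated-normal mixture (~35% overload prevalence), pulse-amplitude
  attenuation r(P) = r_min + (1 − r_min)·σ((P − P₀)/s) linking pressure
  to waveform behavior, and a deliberately weak lognormal BNP
  comparator;
* **beat-level feature extraction**: per-beat amplitude, half-height
  width and area-under-the-curve; per-window means, SDs and RMS power
  over the terminal 5 s of rest and strain; end-Valsalva/end-rest
  ratios;
* a **candidate pool** of 65 features (9 waveform bases + age, all
  squares, all pairwise interactions) with greedy forward selection
  capped at three terms;
* **cross-validated modeling**: OLS regression of filling pressure
  scored by pooled fivefold-CV R²; LDA, logistic regression, KNN,
  decision-tree and RBF-SVM classifiers of volume overload at the
  >15 mmHg cutoff (>10 mmHg sensitivity cutoff) benchmarked against a
  majority-class dummy and BNP-only baselines;
* **reporting**: Bland–Altman limits of agreement and a side-by-side
  comparison table.

## Worked example

```python
import numpy as np
from ppgvol import SimConfig, simulate_cohort
from ppgvol.feature_table import build_candidate_pool, features_from_cohort
from ppgvol.modeling import (
    bnp_only_model, cv_classify, cv_regress, dummy_classify, forward_select,
)

config = SimConfig(seed=7)
subjects = simulate_cohort(120, config)
pool = build_candidate_pool(features_from_cohort(subjects))

trace = forward_select(pool, pool.target, k=3, task="regression")
cv_r2, _ = cv_regress(pool.select(trace.selected).values, pool.target, seed=7)
bnp = bnp_only_model(pool.bnp, y=pool.target, seed=7)
print("selected terms:", trace.selected)
print(f"waveform CV R^2: {cv_r2:.3f}   BNP-only CV R^2: {bnp.cv_r2:.3f}")

cls = forward_select(pool, pool.labels_15, k=3, task="classification", method="lda")
m = cv_classify(pool.select(cls.selected).values, pool.labels_15, method="lda", seed=7)
d = dummy_classify(pool.labels_15, seed=7)
print(f"LDA  accuracy {m.accuracy:.2f}  recall {m.recall:.2f}  AUROC {m.auroc:.2f}")
print(f"dummy accuracy {d.accuracy:.2f}  recall {d.recall:.2f}  AUROC {d.auroc:.2f}")
```

prints

```
selected terms: ['ix(ratio_amplitude,ratio_rms)', 'ix(amp_vals,ratio_auc)', 'ix(ratio_auc,sd_rest)']
waveform CV R^2: 0.936   BNP-only CV R^2: 0.192
LDA  accuracy 0.98  recall 0.94  AUROC 1.00
dummy accuracy 0.70  recall 0.00  AUROC 0.50
```

The forward search lands on interactions of the attenuation ratios —
the physiologic signal the generator encodes — and the waveform model
far outperforms BNP, whose CV R² sits near 0.2 by construction. The
dummy baseline shows the floor an imbalanced cohort hands any
classifier: 70% accuracy with zero recall.

Feature names encode their construction: bare names are base features
(`amp_rest`, `ratio_auc`, `age`, ...), `sq(x)` is a square, and
`ix(x,y)` an elementwise product.

The same pipeline is available from the shell:

```
ppgvol simulate --n 50 --seed 1 --out-dir cohort/
ppgvol extract  --cohort-dir cohort/ --out features.csv
ppgvol fit      --features-file features.csv --case regression --out-dir fit/
ppgvol evaluate --features-file features.csv --report-dir report/
```

All on-disk formats are plain delimited or key-value text (see
`docs/methods.md`).

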