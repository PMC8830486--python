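# neoprog

Quantitative-EEG analysis for predicting later cognitive outcome from
neonatal multichannel EEG, built around adaptive mode decomposition,
phase-based connectivity and signal-complexity features.

Infants who survive neonatal hypoxic-ischemic encephalopathy (HIE) are at
substantial risk of cognitive impairment that only becomes measurable years
later (e.g., as a Bayley-III cognitive composite at age two, population mean
100, observed range roughly 74-145).  `neoprog` implements a regression
pipeline that asks whether resting-state EEG recorded in the first week of
life already carries predictive signal: it cleans and epochs the recordings,
decomposes them into narrowband intrinsic mode functions, derives functional
connectivity and complexity features per mode, screens those features
against outcome scores, and evaluates tree-ensemble predictions under
leave-one-subject-out cross-validation.  Because clinical recordings of this
kind are not publicly distributable, the package ships a first-class
synthetic-cohort generator that plants known oscillations, phase couplings,
complexity gradients, artifacts and score-feature effect sizes, so every
stage is testable end to end.

## Methods at a glance

- **Preprocessing** — band-pass filter (0.5-45 Hz), automatic bad-channel
  removal (flat channels and robust-z SD outliers), common average
  reference, 2-s epochs, rejection of epochs exceeding 55 μV, ICA
  reconstruction `x' = W⁻¹u'` with a pluggable automatic artifact rule, and
  truncation to a common epoch count (default 30).
- **NA-MEMD** — multivariate empirical mode decomposition with an appended
  white-noise subspace.  Signals are projected along K low-discrepancy
  direction vectors on the unit hypersphere; each projection's maxima are
  spline-interpolated into multivariate envelopes whose mean m(t) is
  subtracted during sifting, `c_i(t) = v(t) − m(t)`.  Per channel, every
  subject's epochs are stacked row-wise (an [N_s·N_e] × N_t matrix) so all
  subjects receive frequency-aligned modes.
- **Connectivity** — weighted phase-lag index per channel pair, epoch and
  mode: `WPLI = |E[|Im X|·sign(Im X)]| / E[|Im X|]` with X = Z₁Z₂* the
  analytic-signal cross-spectrum; epoch-averaged matrices become complete
  weighted networks summarized by weighted transitivity, global efficiency,
  radius, diameter and characteristic path length (lengths = 1/weight).
- **Complexity** — per epoch, channel and mode: sample entropy
  `SampEn = −ln(Aᵐ/Bᵐ)` (Chebyshev matches, self-matches excluded),
  normalized permutation entropy of ordinal patterns, and spectral entropy
  of the normalized in-band power spectrum — 3 measures × 12 channels = 36
  features per mode after epoch averaging.
- **Inference** — Pearson r per feature with two-tailed p from
  `t = r√(n−2)/√(1−r²)` (df = n−2), inclusive α = 0.05 screen; bagged and
  least-squares gradient-boosted regression trees under leave-one-subject-out
  cross-validation, reporting RMSE, MAE and pooled R².

**Caveat:** following the original analysis design, the screen applies no
multiple-testing correction across its feature set; on real data its hits
are exploratory.

## Worked example

`python examples/screen_and_predict.py` runs the full chain on a synthetic
8-subject demo cohort (3 channels, 64 Hz, a delta-band regularity gradient
on C3 coupled to the scores) and prints:

```
top entropy features by screen p-value:
       feature     r     t p_value  n  significant
   pen_T3_imf0 -0.71 -2.45   0.050  8         True
   pen_O1_imf0  0.48  1.35   0.225  8        False
  spen_T3_imf0 -0.43 -1.18   0.282  8        False
...
LOSOCV (boosted trees): rmse = 9.82, mae = 8.00, pooled R^2 = 0.19
```

The screen ranks every entropy and graph feature by p-value; `significant`
applies the inclusive p ≤ 0.05 rule.  The LOSOCV block predicts each
subject's score from a model trained on the other seven; a pooled R² above
zero means the screened features beat the constant mean-score baseline on
held-out subjects.  Other examples cover cohort generation, two-tone mode
separation, coupling recovery with graph metrics, and entropy gradients.

The same pipeline is scriptable from a shell:

```bash
neoprog run --profile demo --seed 1 --out out/
neoprog synth --profile delta_recovery --seed 3 --out cohort/
neoprog screen --features features.tsv --scores scores.tsv --out screen.tsv
```

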