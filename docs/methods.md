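# Methods

This note documents the models and procedures `neoprog` implements, the
parameters that matter, what the synthetic cohorts do and do not emulate,
the numerical choices, and known limitations.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pipeline model

The pipeline estimates the association between neonatal resting-state EEG
and a continuous cognitive outcome measured years later, under these
assumptions: (i) the informative EEG structure lives in narrowband
oscillatory components that standard fixed frequency bands may mis-slice,
so decomposition is adaptive (empirical mode decomposition) rather than
filter-bank based; (ii) phase relationships between channels, not
amplitudes, carry the connectivity signal, and zero-lag relationships are
suspect (volume conduction), motivating the weighted phase-lag index;
(iii) signal irregularity per channel carries complementary local
information, captured by entropies in state-space, ordinal and spectral
domains; (iv) the feature-outcome relationship is approximately monotone
and is screened linearly (Pearson) but predicted non-parametrically (tree
ensembles), because with ~20 subjects anything richer overfits.

## Preprocessing

| parameter | default | meaning |
|---|---|---|
| band-pass | 0.5-45 Hz | zero-phase 4th-order Butterworth, applied first; upper edge clipped below Nyquist at low sampling rates |
| `flat_tolerance` | 0.1 μV | SD floor under which a channel counts as flat |
| `noise_sd_multiplier` | 3.0 | robust z ((SD − median)/1.4826·MAD across channels) above which a channel counts as noisy |
| `epoch_length` | 2 s | quasi-stationarity window |
| `amplitude_threshold` | 55 μV | epochs with any channel strictly above it are rejected; exactly 55 μV is retained |
| `n_keep_epochs` | 30 | first-N truncation for a common epoch count |

The noisy-channel rule quantifies "large amount of noise" as a robust
z-score because no numeric criterion exists for it; the robust form keeps a
handful of gross outliers from inflating the scale estimate.  With very few
channels (fewer than ~5) the median/MAD statistics are meaningless, so
reduced profiles disable bad-channel detection
(`bad_channel_detection=False`).

ICA uses FastICA on the concatenated epochs; one component per channel,
except that rank-deficient data (a common average reference removes one
degree of freedom) reduces the component count to the data rank, which
keeps the reconstruction exact.  Manual component classification is
non-reproducible, so the artifact rule is pluggable: the default is
pass-through (reconstruction error ~1e-15), and `"frontal_template"` flags
components whose scalp projection correlates above 0.8 with a
frontal-weighted ocular template.  Every flagged set is logged.

## NA-MEMD

Direction vectors come from a Hammersley low-discrepancy set mapped to the
unit hypersphere through the exact hyperspherical-angle quantile transform
(uniform with respect to sphere measure; in 2-D the directions are exactly
equiangular).  Defaults: K = 64 directions, 2 white-noise channels at 10%
of the pooled signal SD (seeded), natural cubic-spline envelopes with
mirror-extension of the two outermost extrema at each boundary, sifting
stoppage when the envelope-mean-to-detail energy ratio falls below 1e-2 or
after 10 iterations, and a global stop when the remainder is monotonic on
every variate jointly (the per-variate alternative is not implemented;
joint stopping guarantees aligned mode counts trivially).

Decomposition is exact by construction: modes plus residue telescope to
the input (the suite asserts relative error < 1e-8; measured values are at
machine precision).  Mode counts can differ between *channels* (each
channel's stacked matrix is decomposed separately); channels are aligned by
truncating to the minimum count, with dropped tail modes folded into the
residue so completeness is preserved per channel.

Mode selection: the default rule drops the first three modes (broadband,
mixed oscillations) and the last (residue-like), mirroring the retention of
modes 4-9 out of ten on full-scale data.  A band rule keeps modes whose
pooled spectral centroid falls in a frequency interval, and `band_merge`
additionally sums them into one band-limited reconstruction — used when the
oscillation of interest is wider than one quasi-dyadic mode (a band such as
0.5-2 Hz spans more than one octave and will split).

## Connectivity and graph metrics

Instantaneous phases come from the analytic signal; the first and last 5%
of each epoch's samples are discarded before the WPLI expectation to
suppress transform edge artifacts.  The expectation runs over time samples
within an epoch, and the per-epoch matrices are averaged arithmetically.
An identically real cross-spectrum (e.g., identical inputs) gives 0/0,
defined as 0 — absence of *lagged* coupling; numerically this uses a floor
of 1e-10 times the mean cross-spectral magnitude, because rounding noise in
the imaginary part otherwise produces an arbitrary sign ratio.

The per-epoch WPLI estimator has a positive bias for independent signals
that scales inversely with the time-bandwidth product of the epoch: for
octave-wide narrowband noise and 2-s epochs the floor is roughly 0.2-0.3
and does not average away across epochs (each epoch's estimate is already
an absolute value).  Planted-coupling tests therefore assert coupled pairs
≥ 0.9 against independent pairs below that floor, not against zero.
`scripts/acceptance.py` reports both numbers.

Graphs are complete weighted networks — no thresholding.  Path-based
metrics use connection lengths 1/weight (zero weight → unreachable):
characteristic path length is the mean finite off-diagonal shortest-path
distance, global efficiency the mean reciprocal distance (unreachable → 0),
radius/diameter the min/max nodal eccentricity.  Weighted transitivity uses
the cube-root (geometric-mean) triangle-intensity convention over connected
triples.  All metrics are verified against brute-force Floyd-Warshall and
exhaustive triangle enumeration on random graphs.

## Entropy features

| parameter | default | notes |
|---|---|---|
| SampEn m | 3 | recommended range 2-3 |
| SampEn r | 0.2 × epoch SD | recommended range 0.1-0.25; per-epoch SD |
| SampEn delay | 1 | optional template subsampling |
| PEn order n | 3 | ordinal pattern length |
| PEn delay L | 1 | recommended 1-2 |
| PEn normalizer | ln(n!) | ln(n) available as `as_printed_ln_n` |
| SpEn band | 0.5-45 Hz | intersected with the mode's own band content |

SampEn's degenerate no-match case returns the upper bound
ln((N−m−1)(N−m)).  PEn ties are broken by temporal order (stable sort).
The PEn normalizer ln(n!) is the attainable maximum (ln(n) can exceed 1 for
n ≥ 3); the choice rescales by a constant and cannot affect downstream
correlations, so it is cosmetic and recorded in the config snapshot.
Entropies are computed per epoch and averaged, giving 3 measures × channels
features per mode (36 for the 12-channel montage).  Epoch-averaged SpEn on
short windows is noticeably skewed; averaging across epochs is what makes
the Pearson screen's t-based p-values well calibrated (the type-I test
demonstrates this at the 0.05 level).

## Inference

Significance is inclusive (p ≤ 0.05).  No multiple-testing correction is
applied across the feature set, replicating the original design; treat
screen hits as exploratory.  Ensembles default to 30 learners, minimum leaf
8, boosted learning rate 0.1 (regression-learner-style presets; none are
stated in the source analysis), seeded and recorded in every report.
LOSOCV metrics are pooled across the n held-out predictions with SS_total
about the grand mean of the actual scores; per-fold values are logged
alongside because "averaging the independent regression outcomes" is the
other defensible reading.

## Synthetic cohorts

The generator emulates the *statistical shape* of a neonatal resting-state
study: cohort size (default 20), the 12-channel 10-20 montage, 2-s epoch
structure, amplitudes of tens of μV (order-of-magnitude choices,
config-exposed, since no amplitude distribution is published), scores
clipped to 74-145 with the clipping fraction logged (clipping attenuates
planted correlations).  It plants: sinusoidal oscillations; phase-coupled
pairs (narrowband carrier, target = carrier shifted by a fixed lag, mixed
with independent noise at 1 − strength); a per-subject complexity schedule
that either scales broadband noise or sets the tone/noise mixing weight of
a delta-band component; artifacts (flat channels, high-variance channels, a
fraction of supra-threshold epochs, ocular-like low-frequency transients
with a fixed frontal-weighted mixing vector so the ICA stage has a known
target).  Scores are `baseline + slope·z(feature) + N(0, residual SD)`,
giving planted population correlation slope/√(slope² + residual²).

It does **not** emulate neonatal EEG morphology — no burst suppression,
sleep states, 1/f background or volume conduction — so passing tests
demonstrate correct recovery of planted statistical structure, not clinical
validity on real recordings.

## Reduced problem sizes

Full-scale decomposition (12 channels × 600 stacked rows × 1024 samples,
K = 64) is supported but takes hours; the suite and the acceptance script
run declared scaled-down regimes chosen as the package's own working sizes:
a demo profile (8 subjects, 3 channels, 3 × 4-s epochs at 64 Hz, K = 16)
and a recovery profile (20 subjects, 3 channels, one 16-s epoch at 64 Hz,
K = 48, delta plant at 0.5-2 Hz with the full-range mixing schedule,
band-merged delta mode, SpEn evaluated inside 0.5-4 Hz).  Oscillation
separations of at least two octaves are preserved so the quasi-dyadic
filter bank behaves as at full scale.

## Known limitations

- **Measurement attenuation in planted-effect recovery.** The recovery
  experiment couples scores to the spectral entropy of the planted delta
  component at population ρ = 0.6 (n = 20).  The pipeline's measured
  counterpart correlates with the planted feature at roughly 0.9, not 1:
  sifting adaptively strips part of the fast in-band irregularity that the
  entropy quantifies, by a realization-dependent amount.  This attenuation
  is invariant to the direction count, noise-subspace size, sift depth, row
  length and contamination level, and it lowers the screen's per-seed
  detection power from 0.836 (the exact power of the two-tailed Pearson
  test at ρ = 0.6, n = 20) to roughly 0.7.  The acceptance script reports
  the realized recovery rate; the corresponding suite check is strict and
  currently fails at the 80% bar by this margin — an honest property of the
  method at this problem size, not a tunable.
- The per-epoch WPLI bias floor (above) means absolute WPLI values are only
  comparable at a fixed epoch length and bandwidth.
- Printed mode band edges on real data (e.g., a 15-26 Hz fourth mode) are
  dataset outcomes, not parameters; synthetic decompositions are selected
  by centroid band rules instead of fixed mode indices.
- The equivalence of the two cross-spectrum conjugation conventions
  (Z₁Z₂* vs Z₁*Z₂) is noted and harmless: it flips the sign of Im X and
  leaves WPLI unchanged.
- EDF export is not implemented (no EDF writer among the dependencies);
  the documented TSV + JSON array container is the native fixture format
  and round-trips losslessly at 1e-6 μV precision. EDF reading is
  available when `mne` is installed.
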