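# Methods

## Pipeline overview

The pipeline reduces one stress-test recording to one number per phase:

1. **Discriminant series** (`pmld_core`). Both interval series are min–max
   rescaled to [0, 1] over the whole recording, then each centre beat *k*
   and lag *δ* give the β = 1 perfect matrix of Lagrange differences,
   mapped to its discriminant `(a₁₁ − a₂₂)² + 4 a₁₂ a₂₁`. Since
   `a₁₁ − a₂₂ = x_k − y_k`, `a₁₂ = (x − y)_{k+δ}` and
   `a₂₁ = (x − y)_{k−δ}`, the discriminant depends on the two series only
   through their pointwise difference `u = x − y`; identical series give
   exactly zero, which is the formal sense in which the statistic measures
   "similarity of variability". Internal (δ = 1…Ri) and external (window
   radius Re) averaging yields `s_k` for
   `k = 1+Ri+Re … n−Ri−Re`.
2. **Minute features** (`minute_features`). Beats are placed in time by
   cumulative RR (the only clock available in interval data); beat *j*
   belongs to minute `⌈t_j / 60 s⌉`. `s_k` is averaged per minute and
   paired with that minute's relative pulse amplitude `(S − D)/S`. Minutes
   missing either side are dropped. OLS of mean discriminant on relative
   pulse amplitude per phase gives the slope coefficient; Spearman's rank
   correlation (midranks on ties) measures fit quality.
3. **Cohort model** (`cohort_model`). Per group and phase: sample mean,
   n−1 standard deviation, Anderson–Darling normality test, one-sigma
   interval `μ ± σ`. The load-phase variation interval is
   `[μ_high − σ_high, μ_normal + σ_normal]`; a classification is offered
   only where the separation condition `|μ₂ − μ₁| ≥ min(σ₁, σ₂)` holds.
4. **Classifier** (`classifier_triangle`). Linear interpolation of the
   candidate slope into [−1, 1] with cut outliers; branch widths
   `left = round(10 − 9(C+1)/2)`, `right = round(9(C+1)/2 + 1)`, which sum
   to 11 before rounding.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `Ri` | 3 | beats | internal smoothing radius = lag bound δmax |
| `Re` | 4 | beats | external smoothing radius; min series length 2(Ri+Re)+1 = 15 |
| `β` | 1 | – | matrix arrangement; only β = 1 implemented, others rejected explicitly |
| normalisation | on | – | per-series min–max to [0, 1] before matrix construction |
| rounding | 4 d.p., half away from zero | – | reporting convention for tabulated statistics |

The smoothing radii are the published cohort-level optimum and are treated
as fixed; the package does not re-optimise them.

### Why normalise the interval series

Raw RR/JT values in ms give discriminants of order 10⁵ ms², while the
phase-plane slope coefficients of interest are of order 1 — the two scales
are irreconcilable without a normalisation convention, which the original
presentation leaves implicit. This package rescales each series to [0, 1]
over the full recording before matrix construction. This (a) makes the
discriminant dimensionless and invariant to the unit of the input
(verified by a test comparing ms and s inputs), (b) produces the
characteristic collapse of the discriminant to ≈ 0 at peak load, where
both normalised series reach their minima together, and (c) puts
phase-plane slopes on an O(1) scale. `smooth_series` itself stays in raw
units (and is tested against a literal brute-force implementation);
normalisation is applied by the pipeline entry point
`discriminant_profile(..., normalize=True)`.

## Statistical choices

* **Standard deviation** uses the n−1 denominator; this is what reproduces
  the published cohort σ values exactly, as the unit tests check.
* **Anderson–Darling**: A² from `scipy.stats.anderson` (normal, both
  parameters estimated); p-value from Stephens' piecewise-exponential
  approximation applied to the corrected statistic
  `A²(1 + 0.75/n + 2.25/n²)`. The original significance levels were
  evidently produced by a different (unspecified) approximation, so tests
  assert rejection regions and Monte-Carlo type-I calibration, not digit
  equality.
* **Separation condition**: the difference-of-means form
  `|μ₂ − μ₁| ≥ min(σ₁, σ₂)` is implemented; an alternative form appearing
  once with σ in place of μ is inconsistent with the published arithmetic
  and was discarded.
* **Recovery intervals** are computed but refused by the classifier unless
  explicitly overridden, because the separation condition fails on
  recovery data.
* **Variation interval** is carried at full precision; rounding the
  interval ends to 4 d.p. before interpolating would change the fourth
  decimal of C for the worked candidates.

## The synthetic generator

`synthetic_cohort` emulates a graded bicycle test (50 W steps every two
minutes, constant cadence) at the level the analysis consumes:

* **Heart rate**: staged ramp from `rest_hr` (70/75 beats/min) to
  `peak_hr` (165/160), climbing in the first half of each 2-minute stage;
  exponential return with time constant `recovery_tau` (2.5 min).
* **JT interval**: affine in the realised RR beat by beat (JT is
  rate-dependent), shortening toward ~160 ms at peak load, plus a
  repolarisation-hysteresis term that keeps JT above its steady-state rate
  relation while the rate is rising (`jt_lag_amp · p(1−p)^pow` of the
  heart-rate progress *p*, weaker during recovery). Because min–max
  normalisation is affine-invariant, the shared rate component cancels in
  the discriminant exactly; the hysteresis term and JT's own variability
  are the controlled desynchronisation the pipeline measures.
* **Variability**: AR(1) beat-to-beat noise (coefficient 0.3), rest level
  35 ms RR / 14 ms JT, tapering to a 10% floor exactly at peak load and
  rebounding with the heart-rate return. This produces the early rise of
  the minute-averaged discriminant, its minimum in the final load minutes,
  and its restoration during recovery.
* **Pressure**: diastolic near-constant, systolic rising (steeper and from
  a higher baseline, 150/90 vs 115/80 mmHg, for the high-ABP profile),
  readings rounded to integer mmHg with 0.3 mmHg jitter, ceilings
  250/110 mmHg.

### Slope targeting

`generate_cohort` can draw per-person load (and recovery) slope targets
from a Gaussian and calibrate each person's pressure-ramp steepness so the
pipeline-recovered OLS slope matches the draw: the OLS slope is exact
under linear reparametrisation of the x-axis, so only the per-minute
relative-pulse increment needs solving (a quadratic in the realised
reading noise, polished by fixed-point iteration against the quantised
integer-mmHg readings, with a deterministic grid fallback). Steeper
targets get a proportionally stronger desynchronisation amplitude — the
physiological reading is that strongly pressure-dominant responders
collapse earlier and harder — which keeps their discriminant trend
resolvable above the 1 mmHg quantisation floor.

With `moment_match=True` the target draw is a shuffled stratified-quantile
sample whose sample mean and n−1 SD equal the targets exactly. This mode
exists because the load separation condition's margin at the study's
cohort sizes (9 and 10) is only ≈ 7%, so a random draw fails it by
sampling luck in a large fraction of replicates; moment matching makes the
end-to-end test a test of the pipeline rather than of the draw.

### What passing synthetic tests does and does not show

The generator reproduces the statistical structure the analysis assumes —
trend shapes, noise autocorrelation, per-minute sampling, quantised
pressures — not real electrophysiology: no ectopic beats or artefacts, no
respiratory sinus arrhythmia band structure, no ST changes, no
beat-detection error, and JT is generated directly rather than measured
from a waveform. Recovery on synthetic cohorts therefore demonstrates
correctness of the estimation chain, not clinical validity on real
recordings.

## Numerical and edge-case conventions

* Beat indices are 1-based in `build_pmld` and `DiscriminantSeries.k_index`,
  matching the defining formulas.
* The phase of `s_k` is the phase of its centre beat; smoothing windows may
  straddle the load/recovery boundary.
* A minute's phase label is the majority phase of its smoothed beats (ties
  go to load); the pressure reading's label is authoritative in the joined
  feature table.
* Degenerate cases raise typed errors (`SeriesTooShortError`,
  `InsufficientDataError`, `DegenerateFitError`) or attach warnings
  (zero σ, degenerate variation interval) rather than returning silent
  NaNs.
* Pixel widths round half away from zero and clamp to [1, 10]; equal
  rounded widths are reported as a "balanced" tendency.
* Slopes beyond the interval ends clamp to C = ±1 and set an
  `outside_interval` flag in the report.

## Problem sizes

Default test-suite recordings are ~14 load + 8 recovery minutes
(≈ 2 000–2 500 beats per person); the end-to-end cohort experiment uses
the study's sizes, 9 + 10 persons. The Anderson–Darling calibration uses
500 replicates of n = 10. The full suite runs in well under a minute.

## Known limitations

* Only the β = 1 matrix of the 18 admissible arrangements is implemented;
  the constructor rejects other β values explicitly as an extension point.
* The "W·ms" unit attached to slope coefficients is kept as an opaque
  string; it is not dimensionally derivable from the pipeline's inputs.
* Per-person slopes of the published cohort tables cannot be recomputed
  (raw recordings unavailable); they enter as fixtures, and the regression
  operator is validated against closed-form oracles instead.
* The classifier is deliberately not a dichotomous classifier; no
  confusion-matrix/AUC machinery is provided.
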