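# Methods

## The measurement being modelled

After acclimatization in a 23 ± 1 °C room, both hands are covered with thin
plastic bags and immersed in 10 °C water for 60 s; they then rewarm passively
under an infrared camera, which records until the fingers approach their
pre-cooling temperature or 60 min have passed. Elliptical regions of interest
over the dorsal middle phalanx of the eight ulnar fingers yield one
temperature–time curve per finger. Empirically these curves come in two
morphologies: an S-shaped logistic-like rise back toward baseline, and a
"horizontal" trace that barely rewarms. Patients with primary Raynaud's
phenomenon tend to have colder baselines, longer times to their end
temperature, incomplete recovery, and far more horizontal curves than healthy
controls — but with substantial overlap, which is why a multivariable model
is needed at the level of individual diagnosis.

## Curve characteristics

For a cleaned series with baseline window `B` and rewarming time `τ`
(minutes after cooling ends):

* `t_base` — mean temperature over the baseline window (default 1 min of
  samples recorded before the cold challenge, so the quantity is measurable
  from the trace itself).
* `t_0` — the first post-cooling sample.
* `t_end` — mean of the final 2 min of recording (`plateau_window`). The end
  temperature is defined graphically in this tradition; a trailing-window
  mean is a deterministic operationalization that is robust to sensor noise.
* *time to `t_end`* — the first `τ` at which the trace enters and remains
  within 0.5 °C (`plateau_epsilon`) of `t_end`.
* `R% = 100·(t_end − t_0)/(t_base − t_0)`; requires `t_base > t_0`
  (otherwise there was no cooling response and the series is rejected).
* `t_50* = (t_end − t_0)/2 + t_0` — the substitute half-recovery level that
  exists for every curve, including horizontal ones.
* Sigmoid characteristics (S-shaped curves only): the maximum rewarming
  slope is the largest least-squares slope over a sliding window of 5 samples
  (ties to the earliest window); *time to `t_50`* is the linearly
  interpolated first crossing of `(t_0 + t_end)/2`; the lower/upper lag
  times are where the tangent at the maximum-slope point meets the `t_0`
  and `t_end` levels — the standard growth-curve tangent construction. For
  a logistic rise of amplitude `A` and steepness `r` these have closed
  forms (`slope = rA/4`, lags at `midpoint ∓ 2/r`), which the tests exploit.
* Curve type: S-shaped iff `R% ≥ 30` **and** the maximum windowed slope is
  ≥ 0.2 °C/min; otherwise horizontal. No quantitative criterion exists in
  the source tradition; both thresholds are config-exposed
  (`FeatureConfig`). Sigmoid fields are represented as absent (`None`) for
  horizontal curves rather than as sentinel numbers.

Artefact cleaning replaces samples deviating more than 3 °C from a centered
5-sample rolling median by linear interpolation of their clean neighbours
(nearest clean value at the boundaries); a series with more than 20% flagged
samples is rejected. The rule is idempotent and order-preserving.

ROI extraction averages the pixels whose *centers* satisfy the rotated
ellipse inequality; pixel (0, 0) is top-left, x rightward, y downward,
rotation counter-clockwise. Pixel-center membership (rather than
area-weighting) keeps the operation exactly reproducible by an explicit
pixel loop, which the tests use as an oracle. Whether the original analysis
used the within-ellipse mean or another statistic is not documented; the
mean is assumed.

## Subject reduction and hand pooling

Eight feature sets per subject reduce to one: `t_base` and `t_0` by mean,
`t_end` by minimum, time to `t_end` by maximum; `t_50*` and `R%` recomputed
from the selected values (not averaged); curve type S-shaped only if every
finger is. Missing fingers are tolerated with a warning and the count is
recorded; zero fingers is an error.

Pooling left and right hands is justified by a rank-sum test that respects
clustering: within each subject the combined left+right values are ranked
(average ranks for ties) and the statistic sums the centered left-hand rank
sums across subjects. Exchanging a subject's hands flips the sign of its
contribution, so the null distribution is the set of subject-level sign
flips — enumerated exactly for ≤ 12 subjects, by normal approximation above
that. The construction is distribution-free and has an exact small-sample
oracle; its type-I error at the 5% level stays within [0.03, 0.07] in
simulation (2,000 null cohorts of 20 subjects).

## Model development

Candidates: time to `t_end`, `t_base`, `t_0`, `t_end`, `t_50*`, `R%`, curve
type (indicator for horizontal), age. Gender is excluded by default (too few
male patients to support it). Development is:

1. **Alias removal** — greedily drop predictors that are (near-)exact linear
   combinations of higher-priority ones. This matters because `t_50*` is by
   construction the average of `t_0` and `t_end`; a pairwise screen cannot
   see three-way dependence.
2. **Correlation screen** — for every pair with Pearson |r| > 0.75, drop the
   lower-priority member (priority = candidate order).
3. **Backward elimination** — maximum-likelihood logistic fits
   (statsmodels), removing the largest Wald p-value until all remaining
   predictors have p < 0.05 (`p_stay`, config-exposed).

Separation policy: quasi-separated predictors inflate their own Wald
standard errors (the Hauck–Donner effect) and are pruned by the elimination
step itself, so mid-procedure fits tolerate them. A fit whose information
matrix is singular, or a *final* model with a runaway coefficient
(|β| > 50), is flagged as separation. By default this raises an error naming
the offending predictor so an analyst can intervene; inside automated
resampling (`on_separation="drop"`) the strongest univariate separator is
dropped and development continues, since no one can hand-review hundreds of
resamples.

The decision threshold is either fixed or derived from the training ROC by
maximizing Youden's J (`sensitivity + specificity − 1`), ties broken toward
the higher cutoff; "both sensitivity and specificity highest" is not a
formal criterion, and Youden is its standard operationalization. A
probability exactly at the cutoff counts positive (a convention was
required; it is config-exposed). Time is in minutes throughout — the worked
example (coefficient 0.11 with a 60-min axis) only classifies positive under
minutes, and a unit-mismatch test guards this.

The summary table reports estimates, standard errors, Wald z, z², and
p-values. Published Wald statistics in this area are sometimes printed as
χ² while numerically being z values; reporting both avoids asserting either
reading.

## Nomogram

Standard linear-points construction: a predictor's points are
`scale · β · (value − reference)` with the reference at the end of its range
contributing least risk (so points are non-negative), and `scale` chosen so
the widest predictor spans 0–100 points. Total points map to probability
through the logistic link. The lookup is algebraically exact, so the
round-trip error against direct evaluation is far below the 0.01 tolerance
the tests enforce. Zero-coefficient predictors are excluded with a warning.

## Internal validation

* **AUC** — concordance (probability a random case outranks a random
  control, ties ½), computed via scikit-learn and cross-checked in the tests
  by exhaustive pair counting; percentile-bootstrap CI (2,000 seeded
  resamples; degenerate one-class resamples carry no information and are
  skipped).
* **Confusion metrics** — reported at full precision and as whole percent
  (round-half-up). A zero denominator yields "undefined", never 0. The
  reference counts (18/4/49/8) give NPV 49/53 = 92.45%, which rounds to 92
  rather than the conventionally quoted 93; the discrepancy is surfaced in
  the self check and NPV is not gated.
* **Brier score** — mean squared difference between probability and outcome.
* **Calibration intercept/slope** — slope from a logistic regression of the
  outcome on the linear predictor; intercept from an intercept-only logistic
  model with the linear predictor as offset. A model evaluated on its own
  development data gives (0, 1) identically — the "apparent" column.
* **Optimism correction** — Harrell's bootstrap with B = 300 (default): each
  resample reruns the *entire* development procedure, performance is
  measured on the resample and on the original data, and the average
  difference is subtracted from apparent performance. Resamples where
  development fails are skipped and counted; more than 5% failures aborts
  with a diagnostic. A degenerate resample model (constant linear predictor)
  has no defined calibration slope and contributes nothing to that metric.
* **Calibration belt** — polynomial logistic recalibration of the outcome on
  logit(p), degree selected forward by likelihood-ratio tests at 0.05
  starting from 1 and capped at 4 (the cap keeps the fit stable at cohort
  sizes near 80). The deviation test compares the selected curve to the
  identity line by a likelihood-ratio test on the number of fitted
  coefficients; the belt inverts the likelihood-ratio confidence region
  pointwise (SLSQP with analytic gradients) at 80% and 95%. The basis is
  standardized internally for conditioning. The belt requires n ≥ 40 and
  non-degenerate probabilities.

## Synthetic cohort

No patient recordings are distributable, so the generator emulates the
protocol: per-finger traces with 1 min of baseline at `t_base`, a 1-min
linear drop to `t_0`, then either a logistic rise to `t_end` (S-shaped,
steepness `rate`, half-rise at `midpoint` minutes) or a slow linear drift
(horizontal; drift 0.02 °C/min — the residual slope of flat curves is
unquantified anywhere, so this is a free choice). Recording stops when the
noiseless trace comes within 0.5 °C of `t_base` ("approached pre-cooling
temperature" is unquantified; ε is config-exposed) or at 60 min. Sampling is
0.1 min — fine enough for lag-time extraction, coarse enough for speed; the
camera's true frame rate is not public. Gaussian measurement noise
(default SD 0.1 °C) is added after the stopping rule so truncation is
deterministic in the profile. Curves are deterministic given (profile,
seed); cohorts are deterministic given the cohort seed via spawned
per-subject streams.

Group-level defaults (22 patients / 57 controls, 8 fingers each) encode the
clinical picture with deliberate overlap: controls
`t_base ~ N(31.5, 1.2)` °C, cooling drop ~ N(10, 1) °C, recovery deficit
~ N(0.8, 0.5) °C, midpoint ~ N(4.5, 2) min, median rate 1.0 /min, 5%
horizontal; patients `t_base ~ N(30.2, 1.4)`, drop ~ N(9, 1), deficit
~ N(2.2, 1.4), midpoint ~ N(12, 6), median rate 0.7 /min, 30% horizontal.
Finger values jitter around subject-level draws (SD 0.3 °C), giving the
within-subject clustering the rank-sum test needs; a subject's fingers share
one curve type. These sizes reproduce the reference setting's behaviour:
development retains time to `t_end` (+) and `t_base` (−), apparent AUC lands
around 0.85–0.95 across seeds, corrected calibration slopes around 0.8–0.9,
and Brier scores near 0.1. Ages are N(57, 11) in both groups, matching the
absence of an age difference between them.

What the generator does **not** emulate: tissue heat-transfer physics,
room-temperature drift, hand motion in rendered frames, inter-observer ROI
variation, or repeat visits. Passing tests therefore demonstrate the
pipeline's correctness and the statistical machinery's calibration under a
plausible data-generating process — not clinical performance on real
thermograms.

Optional frame rendering paints each finger as a constant-temperature
ellipse on a room-temperature background (multi-page float TIFF plus a YAML
sidecar with timestamps and ellipse parameters), so the ROI-extraction stage
can be exercised end-to-end; rendering followed by extraction reproduces the
source series to 10⁻⁶ °C without noise.

## Numerical choices and degenerate inputs

* Logistic fits: statsmodels Newton (maxiter 200); non-convergence is an
  error carrying the iteration limit.
* Sliding-window slopes are computed by vectorized least squares on the
  uniform grid; a window longer than the series is an error.
* The feature grid tests sample at 0.05 min: the windowed-slope estimate has
  an O((rΔ)²) discretization bias (~1% at r = 2 /min and Δ = 0.1 min), so
  fast rises are tested on a finer grid, mirroring what one would do with a
  real high-rate camera.
* Empty ROIs, mismatched timestamp counts, duplicate ROI labels, unpaired
  fingers, single-class outcomes and constant screening columns all raise
  typed errors naming the offending object.

## Problem sizes used by the test suite

Simulation-backed checks run at sizes chosen to make their Monte Carlo error
small relative to the tolerance being asserted: coefficient recovery at
n = 4,000; calibration-belt level/power at 100 replicates of n = 5,000;
clustered rank-sum level at 2,000 cohorts of 20 subjects; the optimism
property at 50 replicates of n = 40 with B = 40–100 resamples; the full
pipeline demo at the reference cohort size (22/57, B = 25–300).

## Known limitations

* The sigmoid characteristics are extracted nonparametrically (windowed
  slopes and tangent lags) rather than by refitting a parametric
  growth-curve model; for noiseless logistic inputs both agree to within 2%,
  but heavily corrupted curves may differ.
* The calibration-belt deviation test takes the selected polynomial degree
  as given; the forward selection's own multiplicity is not folded into the
  null distribution. At the cohort sizes used its empirical level is
  conservative (the level test passes with margin).
* The clustered rank-sum test's normal approximation is used above 12
  subjects; for 13–20 subjects an exact enumeration would still be feasible
  but is not the default.
* `bootstrap_validate` reruns whatever development function it is given; if
  that function itself fixes the predictors (no screen/elimination), the
  optimism estimate reflects only coefficient re-estimation, as usual.
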