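# Methods

## Scope and model of the data

`occfall` evaluates one-class (novelty-detection) classifiers as the
decision core of a wearable fall detector. The unit of analysis is a
*trace*: one recording of a waist-worn triaxial accelerometer, labeled
ADL or FALL. ADLs additionally carry an intensity category —
*basic* (low-effort postural movements), *standard* (walking-level
routines), *sporting* (vigorous, brusque or repetitive movements) — used
only by the ablation protocol; falls carry no category.

All analysis is accelerometer-only and unit-normalized to g
(1 g = 9.80665 m/s²). Time is implicit (sample index over sampling rate);
no resampling is performed, so traces at different rates coexist in one
dataset and each contributes a window of its own N_W.

## Observation window and features

For a trace with samples aᵢ = (Axᵢ, Ayᵢ, Azᵢ), the signal magnitude
vector is SMVᵢ = ‖aᵢ‖₂. Feature extraction uses only the N_W = round(2·f_s)
samples centered on the first occurrence of the global SMV maximum
(the impact, for falls; the most violent instant, for ADLs). When the
centered range overflows a trace edge it is shifted inward so the window
keeps its full 2-s duration and still contains the peak; traces shorter
than N_W are edge-replicated. The 2-s duration is a standard trade-off
between recognition speed and accuracy for human-activity windows, and
comfortably covers a fall impact, which lasts at most about 0.5 s.

The twelve candidate statistics (window samples aᵢ, magnitudes
mᵢ = SMVᵢ):

| ID | definition | notes |
|----|------------|-------|
| A | mean(m) | |
| B | maxᵢ ‖aᵢ₊₁ − aᵢ‖₂ | max vector change between consecutive samples |
| C | sd(m), denominator N_W − 1 | |
| D | meanᵢ arccos(aᵢ·aᵢ₊₁ / (‖aᵢ‖‖aᵢ₊₁‖)) | zero-norm pairs contribute 0 |
| E | meanᵢ \|mᵢ₊₁ − mᵢ\| | |
| F | meanᵢ ‖aᵢ − (aᵢ·ĝ)ĝ‖ | ĝ = normalized window-mean acceleration; the component parallel to the floor plane |
| G | max(m) | impact peak |
| H | min(m) | free-fall valley |
| I | sample skewness g₁ of m | 0 when C = 0 |
| J | meanᵢ (\|Axᵢ\| + \|Ayᵢ\| + \|Azᵢ\|) | signal magnitude area |
| K | Σᵢ mᵢ² | energy |
| L | mean over lags 1..N_W−1 of the biased normalized autocorrelation of m − mean(m) | 0 when C = 0 |

Design notes on the reconstructions among these: D is computed from
consecutive accelerometer vectors rather than a gyroscope so the pipeline
stays accelerometer-only; F's floor plane is defined through the
window-mean gravity estimate, the simplest gravity proxy; I is the
standard biased g₁; L's estimator is the biased normalized
autocorrelation averaged over all positive lags. Degenerate zero-variance
windows map I and L to 0 to keep vectors finite.

Features are z-score normalized with mean/sd **fitted on the training
partition only** and applied unchanged to test partitions — the
train-fitted choice prevents leakage. Columns with training sd below
1e-12 use sd = 1 (constant features normalize to zero). The two preset
input sets are `BCDFGIK` and `ABCDEFGHIJKL`; arbitrary ID subsets are
accepted.

## One-class models

All five scorers share one orientation — larger score = more anomalous —
so a single threshold sweep serves every kind. Likelihood-type scores
(PPNN, OC-SVM decision values) are negated to conform.

- **Autoencoder** (implemented here in NumPy): one hidden layer of
  {6, 10, 12, 15} units, logistic sigmoid encode and decode, inputs
  affinely mapped per column into [0.1, 0.9] by training min/max. Loss =
  reconstruction MSE + 0.001·½Σw² (L2) + 1·Σⱼ KL(0.05 ‖ ρ̂ⱼ) (sparsity of
  mean hidden activations, target proportion 0.05). Trained full-batch
  with Adam (lr 0.01) for 1000 epochs; the training contract is
  "minimize the stated loss for at most 1000 epochs", and any full-batch
  gradient method meeting the scoring properties is acceptable. Score:
  per-row mean squared reconstruction error in the scaled space; sigmoid
  outputs cannot follow queries outside [0, 1], so far-out points score
  high by construction. Deterministic in the seed.
- **GMM** (scikit-learn `GaussianMixture`): diagonal covariance,
  {3, 5, 7} components, k-means++ initialization, variance floor 1e-6
  (prevents singular components on duplicated rows), tol 1e-6, ≤ 500 EM
  iterations. Score: negative log-likelihood.
- **PPNN** (implemented here): Parzen-style kernel scorer,
  likelihood(x) = (1/N) Σⱼ f(−‖x − xⱼ‖²/(2σ²)) with window function
  f(u) = e^{u−1}. The bandwidth σ defaults to the median pairwise
  training distance / √2 (configurable); a degenerate all-duplicates
  training set has zero bandwidth and is rejected unless an explicit
  bandwidth is supplied.
- **OC-KNN** (scikit-learn `NearestNeighbors`): score = distance to the
  k-th nearest training row, k ∈ {5, 10, 50}, distance ∈ {euclidean,
  minkowski (exponent 3, so it differs from euclidean), chebychev,
  cosine}. Combinations with k exceeding the fold's training size are
  disqualified by the grid search rather than silently truncated.
- **OC-SVM** (scikit-learn `OneClassSVM`): ν-formulation with ν = 0.05
  (the training ADL sets are treated as clean; the outlier fraction is a
  documented choice, not a fitted value). Kernels: linear;
  quadratic/cubic = (1 + x·y)^{2,3}; "medium gaussian" = RBF with kernel
  scale √P for P features (gamma = 1/P). Score: negated decision
  function, so the learned boundary sits at score 0. Note the geometry:
  linear and polynomial kernels carve halfspaces anchored at the feature-
  space origin and cannot enclose a centered cloud; on z-scored features
  they only succeed when falls leave the ADL cloud in a consistent
  direction. The grid search is what arbitrates this per dataset.

## Evaluation protocols

**Threshold sweep.** 2500 linearly spaced thresholds spanning the pooled
test scores (the extreme thresholds therefore attain Se = 1 and Sp = 1
respectively). Decision rule: score ≥ τ ⇒ fall. Se(τ) = fraction of fall
scores ≥ τ; Sp(τ) = fraction of ADL scores < τ. AUC is the trapezoidal
area under (1 − Sp, Se) with (0,0) and (1,1) endpoints appended. The
optimal cut-point τ* maximizes G = √(Se·Sp) (smallest threshold on ties).
τ* is selected on the test fold — an optimistic convention replicated
deliberately; an honest mode (τ* chosen on an inner split of 20% of
training-partition ADLs plus half the falls, metrics reported on the
rest) is available behind the `honest_threshold` flag.

**Cross-validation.** ADLs are split into k = 5 partitions stratified by
activity type (seeded shuffle within type, round-robin deal with a
running cursor), so every type with ≥ 5 traces appears in every
partition — the "fair" condition. Per fold: 4 partitions of ADLs train
(normalizer + model), the reserved partition plus **all** falls test.
Falls never enter training, which is asserted structurally. Reported
aggregates are the mean ± sd (ddof = 1) over the 5 per-fold values; in
particular the G column is the mean of per-fold G*, not G of the mean
Se/Sp.

**Grid search.** Every hyperparameter × feature-set combination is
cross-validated; the winner maximizes mean G, ties broken by higher mean
AUC, then grid-enumeration order. Combinations that fail to train on any
fold are disqualified but retained in the report with their error.

**Ensemble.** The three configurations with the highest mean G (across
model kinds; they may share a kind) vote per fold, each thresholded at
its own per-fold τ*; a movement is a fall on ≥ 2 votes.

**Ablation.** For each held-out category c: train on the ADLs of the
other two categories (normalizer refit on that training set), test on
all falls plus the ADLs of c, classify with the fair-case threshold —
the median of the winning combination's five per-fold τ* (the fold-to-
single-threshold distillation is a package choice; median is robust to
one outlying fold). Report Se, Sp, G and Loss = G − G_fair. Note the
threshold is *not* re-optimized, so a shifted score scale after
retraining maps directly into Se/Sp changes — that is the phenomenon
under study. Categories with no ADLs are skipped with a warning.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
not biomechanics. Every trace is gravity (1 g along a per-subject
orientation unit vector) + an activity component + white Gaussian noise
(default sd 0.03 g per axis; sensor noise is not otherwise
characterized). Defaults: 100 Hz, 15 s traces, 20 ADLs per category,
30 falls, 8 subjects; each subject carries one multiplicative amplitude
factor from [0.8, 1.2] — the simplest heterogeneity that makes
subject-blind folding meaningful.

- *basic*: band-limited fluctuation (0.3–1 Hz) of total amplitude
  0.02–0.08 g; with probability 0.5, one smooth posture transition
  (spherical interpolation of the orientation over 2 s, plus a ≤ 0.2 g
  transient), keeping peak SMV ≤ 1.3 g. The orientation rotation is what
  exercises the rotation-angle feature D.
- *standard*: periodic component, fundamental 1.5–2.5 Hz, one harmonic
  at 0.15 of the fundamental, waveform peak-normalized to an amplitude
  drawn from 0.2–0.5 g — the normalization pins the stated peak-SMV
  envelope of [1.0, 1.6] g.
- *sporting*: same construction with fundamental 2.5–3.5 Hz and
  amplitude 0.8–2.0 g, plus sporadic raised-cosine spikes (rate 0.3/s,
  width 0.08–0.16 s, amplitude 0.3–1.2 g) driving peaks toward ~4 g.
- *falls*: four consecutive phases — quiet pre-fall; free-fall with SMV
  decaying smoothly from 1 g to a floor drawn from [0.1, 0.4] g over
  0.3–0.5 s; a half-sine impact spike peaking at 3–6 g within ≤ 0.4 s
  (odd sample count so one sample attains the exact peak); rest at a new
  fixed orientation under reduced noise. The impact center lands at
  45–70% of the trace. The global SMV maximum is inside the impact by
  construction.

These ranges were chosen once so that the qualitative orderings the
analysis relies on hold: fall SMV maxima stochastically dominate basic
ADL maxima, SMV variability orders basic < standard < sporting, and
sporting traces are the only ADLs that intrude into the falls' feature
region when left out of training.

**What passing on synthetic data does and does not show.** The generated
classes are cleanly separable, so fair-case metrics saturate at or near
1.0 — higher than the 0.90–0.99 range real repositories produce. Passing
demonstrates that the protocols are implemented correctly and that the
qualitative ablation findings (sporting hold-out collapses specificity;
basic/standard hold-outs cost little) emerge from the pipeline; it does
not demonstrate real-world detection rates, robustness to sensor
artifacts, orientation drift, or the long tail of real ADL diversity,
none of which the generator models.

## Numerical choices and edge cases

- Peak, τ* and grid-winner ties all resolve to the first candidate in
  deterministic enumeration order.
- A degenerate sweep (all scores identical) widens the threshold range
  by a relative 1e-9 so the grid stays strictly increasing.
- Trace CSVs are written at 12 significant digits (round-trip error
  < 1e-10 g, well inside the 1e-9 contract).
- Model bundles serialize hyperparameters + training matrix + seed and
  retrain on load (deterministic), keeping persistence plain JSON.
- No multiple-testing correction is applied anywhere; reported metrics
  are raw, as is conventional for this evaluation design.
- The feature-matrix CSV export includes an `activity_type` column in
  addition to `trace_id,label,category` + feature IDs, so fair folds can
  be reconstructed from the export alone.
- The full run-report JSON is byte-stable for a fixed config + seed
  (sorted keys, no timestamps; wall-clock details go to `run.log`).

## Known limitations

- The synthetic fall model is phase-templated; it contains no pre-impact
  flailing, bounce, or post-impact movement, and fall variability is
  limited to the drawn phase parameters.
- Adapters for specific public repositories are out of scope; external
  data enters only through the manifest format, and multi-sensor
  repositories must be reduced to a waist accelerometer channel upstream.
- The autoencoder optimizer is a fixed-budget full-batch Adam; no early
  stopping or validation split is used inside model training.
- Scores are not calibrated across folds or models; the ensemble relies
  on per-member thresholds rather than score fusion.
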