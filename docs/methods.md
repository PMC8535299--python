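# Methods

## Problem and pipeline

The package predicts a binary diabetes outcome from 8 clinical features
shared by Pima-style and NHANES-style tables. The workflow is: merge the
source tables (data-level fusion), convert physiologically impossible zeros
to explicit missing values, impute and standardize, train two base
classifiers, fuse their posterior probabilities, and estimate performance
by stratified nested cross-validation.

## Data fusion

Operational fusion is schema-aligned concatenation (Data In–Data Out):
records from every source are stacked with their source tags, optionally
collapsing exact duplicates (off by default — the canonical two-source
cohort sizes 9858 + 769 add to 10,627 with nothing removed). Dempster–Shafer
combination of basic probability assignments — conflict
`K = Σ_{A₁∩A₂=∅} m₁(A₁)m₂(A₂)` and the normalized combined mass
`m(X) = (1/(1−K)) Σ_{A₁∩A₂=X} m₁(A₁)m₂(A₂)` — is provided as a general
evidence utility (`diabfuse.evidence`). It is deliberately *not* applied
per record: there is no defensible mapping from the clinical features to
per-record mass functions, so coupling the two would be invented structure.
Combination with totally conflicting evidence (K = 1) raises an error
rather than returning an arbitrary renormalization.

## Missing values and standardization

Zeros in Glucose, BloodPressure, SkinThickness, Insulin and BMI encode
"not recorded" in Pima-style files and are converted to missing explicitly
by `mark_missing` (configurable; pregnancies, pedigree and age keep their
zeros). Missing cells are filled with the per-feature arithmetic mean of
the *training* records; features are then Z-scored with the training mean
and sample (n−1) standard deviation. Both transforms are fitted objects
applied unchanged to held-out data.

A deliberate design choice: although the nominal stage order is
fuse → preprocess → cross-validate, fitting imputation/standardization on
the full dataset would leak held-out information into the training
statistics. All preprocessing is therefore fit inside each cross-validation
training fold, and the nested-CV report records the per-fold statistics so
the property is testable.

## Base classifiers

**SVM.** The soft-margin dual is solved by libsvm (via scikit-learn) on a
kernel matrix computed in-package; the four kernels are linear `xᵀz`, RBF
`exp(−γ‖x−z‖²)` (default, γ = 1/d), polynomial `(γxᵀz + r)^d`, and sigmoid
`tanh(γxᵀz + r)`. The returned model stores support vectors, signed dual
coefficients and bias, and is checked against the dual box and equality
constraints independently of the backend; on small problems the dual
objective is compared with a scipy SLSQP solve in the tests. Defaults
C = 1, γ = 1/d, overridable by grid search. Class 1 maps to y = +1.

**Posterior extraction.** Platt's two-parameter sigmoid is fit by damped
Newton iterations with smoothed targets `t₊ = (N₊+1)/(N₊+2)`,
`t₋ = 1/(N₋+2)` and fixed initialization A = 0, `B = ln((N₋+1)/(N₊+1))`,
so calibration is deterministic. `CalibratedSVM` fits the sigmoid on
3-fold out-of-fold decision values: calibrating on the final model's own
training decision values is biased toward overconfidence, which measurably
distorts the fusion layer in the no-signal regime (the fused decision then
drifts several points below the majority rate). With out-of-fold
calibration an uninformative score maps to roughly the class prevalence,
as it should.

**ANN.** A single-hidden-layer network (default h = 8, logistic sigmoid
everywhere, one output unit read as P(class 1 | x)) trained by classic
per-sample backpropagation on the half-SSE loss with learning rate λF
(default 0.5), uniform(−0.5, 0.5) seeded initialization, a seed-shuffled
visiting order per epoch, and optional early stop when the epoch SSE
improves by less than `tolerance`. The update direction is plain gradient
descent on E; the analytic deltas are verified against central finite
differences (rtol 1e-6) in the test suite, which is the ground truth for
any sign-convention ambiguity. No momentum, mini-batches or regularization:
the point is the textbook algorithm, implemented exactly.

## Fusion decision layer

Member posteriors are clipped to [1e-12, 1−1e-12] and combined by the mean
rule (min, max, product also implemented; product ≤ min ≤ mean ≤ max always).
Two decision criteria are exposed because the operating point can be defined
either way:

* **mean_posterior** (default): label 1 iff μ(φt|x) ≥ μ(φo|x). For the mean
  rule over two classes μ(φt|x) + μ(φo|x) = 1, so this is the parameter-free
  0.5 threshold.
* **density_threshold**: Yavg(x) < θ̄ declares an outlier, with
  θ̄ = (P(φo)/P(φt))·mean(θᵢ). Yavg is reconstructed from posteriors as
  `mean posterior / P(φt)`; the common evidence density P(x) cancels out of
  the comparison and is dropped, so Yavg is defined up to a positive factor
  that the tunable θ̄ absorbs. θᵢ defaults to 1 per member; priors default
  to training-class frequencies.

Equality at either boundary goes to the target class (the outlier criterion
is the strict inequality). `sweep_threshold` tabulates FPR/FNR over a θ̄
grid; FNR is non-decreasing and FPR non-increasing in θ̄ by construction.

## Validation

`stratified_kfold` assigns each class's shuffled indices round-robin, which
bounds every fold's class-1 share within 1/(fold size) of the overall
share. Nested CV uses outer K = 5 and an inner 3-fold grid search scored on
accuracy (ties break by grid order). Default grids:
C ∈ {0.1, 1, 10, 100} × γ ∈ {0.01, 0.1, 1/d, 1};
h ∈ {4, 8, 16} × λF ∈ {0.1, 0.5}; `GridSpec.small()` is a 2×2 desk-scale
variant used by the quick pipelines. Fold aggregates are mean ± sample SD;
because published tables are sometimes pooled over folds instead, the
report carries both forms. One global seed is fanned out per stage via
CRC32 of "seed:stage", so every stage is independently reproducible.

## Synthetic data

The generator emulates the study conditions, not real patients: per source,
labels are Bernoulli(prevalence = 0.335) and features are independent
class-conditional Gaussians whose class-0/class-1 profiles loosely mimic
published Pima class summaries (higher glucose, BMI, age, pregnancies in
the diabetic class). Values are clipped non-negative, ages clipped to
[21, 77], and integer features rounded. `separation` scales the class mean
gap (0 = no signal, 1 = default overlap, ≥3 = near-separable);
`missing_rate` blanks eligible cells independently.

What it does *not* emulate: feature correlations (an optional hook is out
of scope), skewed/zero-inflated marginals (real insulin is heavily
right-skewed), label noise, and source-specific distribution shift. Passing
tests therefore demonstrate the *mechanics* of the pipeline under
controlled conditions, not clinical performance; in particular the
published-scale headline accuracy on real fused cohorts is outside what
this generator can or should reproduce.

A consequence worth stating plainly: on these independent-Gaussian
conditions the SVM and ANN make highly correlated errors, so posterior-mean
fusion tracks the better standalone member to within a fraction of a
percentage point (sometimes just below it) rather than strictly improving
on it. The improvement claim associated with fusion should be read as
conditional on members with complementary error structure, which this
generator deliberately does not manufacture.

## Numerical choices

* Percentages and reported metrics are rounded half-away-from-zero to two
  decimals at presentation only; internal values keep full precision.
* Zero-denominator metric ratios are reported as NaN with a warning, never
  silently zeroed.
* Mass-function invariants use a 1e-9 tolerance on Σm = 1; K within 1e-9 of
  1 counts as total conflict.
* SVM training uses libsvm tolerance 1e-6 and asserts dual feasibility at
  1e-3; standardization requires strictly positive per-feature variance and
  fails loudly on constant features.
* Problem sizes in the test and acceptance runs (hundreds to a few thousand
  records, 2×2 grids, ≤100 ANN epochs) are the package's own desk-scale
  defaults chosen to keep full nested CV interactive; all are configurable
  upward.

## Known limitations

* No multi-class support; the decision layer is strictly two-class.
* The sigmoid kernel is not positive semi-definite for all parameter
  settings; no PSD check is attempted.
* Platt calibration assumes the decision-value/label relation is reasonably
  sigmoidal; heavily multimodal scores would miscalibrate.
* Dempster combination and dataset concatenation are independent tools; the
  package does not invent a per-record bridge between them.
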