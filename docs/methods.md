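# Methods

## Model

`varmkl` classifies single nucleotide variants as pathogenic (+1) or neutral
(−1) from several annotation sources ("feature groups") by multiple kernel
learning. Each group l yields a base kernel K_l over the training variants;
the classifier is a soft-margin SVM on the composite kernel

    K(λ) = Σ_l λ_l K_l,   Σ_l λ_l = 1,   λ_l ≥ 0.

Writing J(λ) for the optimal value of the SVM dual on K(λ),

    J(λ) = max_α Σ_i α_i − ½ Σ_ij α_i α_j y_i y_j K(λ)_ij,
           0 ≤ α_i ≤ C,  Σ_i α_i y_i = 0,

training minimizes J over the simplex. J is convex and differentiable with
∂J/∂λ_l = −½ dᵀ K_l d at the optimal signed duals d_i = α_i y_i, so the
solver alternates an exact dual solve (libsvm via scikit-learn's
`SVC(kernel="precomputed")`, tolerance 1e−7) with a reduced-gradient descent
step on the simplex in the SimpleMKL style: the largest-weight coordinate is
the reference, zero-weight coordinates with outward-pointing reduced
gradients are frozen, and a halving line search from the largest feasible
step accepts only strict objective decreases. The objective trace is
therefore non-increasing by construction (asserted in the tests). Weights
start uniform at 1/p; the loop stops when the relative objective drop falls
below 1e−5, the weight update falls below 1e−4 in max-norm, no decreasing
step exists, or after 100 outer iterations. The procedure is deterministic.

## Base kernels

Per feature group, on the training rows: each feature column is
standardized to zero mean and unit variance (constant columns are zeroed),
missing cells are imputed at the feature mean (zero post-standardization),
and the kernel is computed — linear inner products by default, or
exp(−γ‖x−y‖²) with γ from the median pairwise-squared-distance heuristic.
Kernels are unit-diagonal normalized, K(i,j) ← K(i,j)/√(K(i,i)K(j,j)) with
0/0 → 0, so groups of very different dimensionality contribute on
comparable scales before weighting. Linear kernels are the default because
the training sets in this setting are small (hundreds to a few thousand
variants) and the interpretation of λ as per-source relevance is cleanest
when no bandwidth interacts with it. Base kernels are validated symmetric
(1e−9) and positive semidefinite (smallest eigenvalue ≥ −1e−8 · largest).

## Missing feature groups at prediction time

A variant lacking every value in a group is scored with that group's weight
set to zero and the remaining weights renormalized to sum to one,
λ'_l = λ_l / Σ_available λ_l; the bias is unchanged. A variant with no
available positively-weighted group cannot be scored and yields an explicit
no-prediction marker (NaN) that propagates through posteriors, predictions
and reports ('.' in CLI output). Value-level (per-cell) missingness is
instead handled inside the kernel by mean imputation; only whole-group
absence triggers rescaling.

## Confidence and cautious classification

Decision values are mapped to posteriors by P(y=1|φ) = 1/(1 + exp(aφ + b)),
fitted by minimizing the cross-entropy against the smoothed targets
t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2) with a damped (backtracking) Newton
iteration; the fit is deterministic and the slope is negative whenever
positives score above negatives, so the posterior increases with φ. The
sigmoid is fitted on out-of-fold decision values (3 stratified folds by
default, each fold's model retrained from the corresponding gram
submatrices) rather than on in-sample φ, which would be overconfident. For
speed the feature scalers are fitted once on all training rows and the fold
models reuse submatrices of the full gram; the leakage this admits affects
only the calibration data, not the final model, and is negligible at the
sample sizes involved. Predicted labels come from sign(φ) with the tie
φ = 0 mapped to +1 (consistent with the at-or-above threshold convention);
near the boundary the sigmoid's P = 0.5 point need not sit exactly at
φ = 0, so a low-confidence prediction can disagree with the posterior's
majority side — cautious classification removes exactly these cases.
Confidence is max(P, 1−P) ∈ [0.5, 1]; a cautious subset keeps records with
confidence at or above the cutoff.

## Regularization constant

When C is not fixed by the user it is selected from {0.01, 0.1, 1, 10, 100}
by out-of-fold AUC on the training set (3 stratified folds, seeded); exact
ties prefer the smaller C. Smaller C values produce sparser kernel weights
(the margin term dominates and the solver concentrates on the single best
kernel), larger values spread weight; the AUC criterion arbitrates.

## Dataset assembly

Benchmark construction follows the standard pathogenic-versus-control
conventions, all implemented as order-preserving, idempotent filters on
1-based VCF-style biallelic SNV records keyed by (chrom, pos, ref, alt):
controls are kept when their global minor allele frequency is ≥ 1%
(inclusive; controls without a MAF are dropped with a logged count, or
rejected on request); controls colliding with a pathogenic key are removed;
negatives may be restricted to those within a symmetric, inclusive 1000-nt
window of some positive on the same chromosome (the distance-to-nearest
reading; window 0 keeps exact-coordinate matches, window ∞ keeps any
negative sharing a chromosome with a positive); datasets split by the
coding flag, which is an input annotation, not recomputed from transcripts;
and training sets are restricted to variants with data in every selected
feature group, optionally balanced by uniform seeded sampling without
replacement per class. Multi-allelic sites and indels are out of scope.

## Synthetic benchmark generator

The generator emulates the structure such studies rely on: per-group
class-conditional multivariate normal features with identity covariance,
where a signal group separates the two latent-class means of every feature
by `effect_size` standard deviations (per-feature separation; a group of m
features has Euclidean class-mean distance effect_size·√m) and noise-only
groups carry no shift; group-level and cell-level missingness at
configurable rates; allele frequencies drawn from Beta models truncated to
the minor-allele range — Beta(2, 5) for clean controls (common variants)
and Beta(1, 19) for pathogenic variants and for the contaminated fraction of
controls that are secretly pathogenic-like (default 5%), so the
low-frequency shift of confident false positives is reproducible by
construction; and genomic positions drawn so a configurable fraction
(default 80%) of negatives falls within 1000 nt of some positive. Default
study conditions are 200 variants per class with four 8-feature groups, one
informative at effect size 2.

What the generator does not emulate: real annotation features are
heterogeneous (binary peak indicators, bounded scores, heavy tails) and
correlated within and across groups; real missingness is structured by
genome region rather than independent per variant; linkage makes labels
spatially correlated. Passing tests on this generator therefore demonstrate
the correctness and qualitative behaviour of the machinery — weight
concentration on informative sources, the coverage/accuracy trade-off, the
contamination diagnostic — not performance figures transferable to real
cohorts.

## Evaluation conventions

A score at or above the threshold is a positive prediction. The threshold
sweep evaluates every distinct observed score plus one sentinel above the
maximum — an exact grid, since no intermediate threshold changes any count
— and reports balanced accuracy (mean of sensitivity and specificity) and
false-positive rate per threshold, with the optimum at the smallest
threshold achieving maximal balanced accuracy. AUC is the Mann–Whitney
statistic computed from midranks, ties contributing one half. k-fold splits
delegate to scikit-learn's (Stratified)KFold with explicit seeds. The
binomial sign test is the exact one-sided tail P(X ≥ wins), X ~
Binomial(n, ½), with ties excluded beforehand. The MAF-shift diagnostic
splits labeled negatives at a posterior cutoff and compares normalized MAF
histograms (25 bins of width 0.02 on [0, 0.5]) of confident false positives
against the rest; a positive mean shift flags enrichment of mislabeled true
positives among the controls.

## Numerical choices and degenerate inputs

Kernel PSD tolerance is relative (1e−8); the simplex invariant is enforced
at 1e−9. Constant feature columns standardize to zero and contribute
nothing; an all-constant group produces a zero kernel, which the simplex
step will down-weight. Posterior evaluation is overflow-safe for |φ| up to
machine range. Platt fitting raises a convergence error carrying the last
iterate rather than returning silently. Training requires both classes;
balanced sampling errors when a class has no complete examples; cautious
cutoffs must lie in [0.5, 1] (the posterior cutoff 0.26 used for ranked
output tiers applies to P itself, not to confidence).

## Problem sizes

The test suite and the acceptance script run the full pipeline at reduced
scale chosen to exercise every code path with stable statistics: 20-seed
replications at 200 training variants per class for weight recovery, 800
held-out variants for cautious-classification curves, 300 held-out
negatives per run for the contamination diagnostic. These sizes are the
package's own defaults for its synthetic studies; the algorithms scale as
O(n²) memory and roughly O(n³) time in the number of training variants via
the kernel matrices, which is the usual practical envelope for kernel MKL
(a few thousand training examples).

## Known limitations

- The inner dual solve inherits libsvm's tolerance; decision-value
  reproducibility across training-row permutations is ~1e−6, not exact.
- Kernel weight estimates are not unique when base kernels are collinear
  (duplicated kernels split weight arbitrarily; the decision function is
  unaffected, which is what the tests pin down).
- Calibration quality degrades when the training set is small or
  single-sided; posteriors are then poorly resolved near 0 and 1.
- Rescaling weights for missing groups assumes the available groups'
  similarities remain informative in isolation; with highly complementary
  groups this degrades gracefully but measurably.
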