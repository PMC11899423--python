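# Methods

This note documents the models, numerical choices and limitations of
`nirclda` at the level of detail a maintainer or reviewer needs.

## Common-vectors LDA

Given training spectra x ∈ ℝᵈ in C classes with M = ΣNᵢ samples and
d > M − C, the within-class scatter S_W = AAᵀ (A's columns are the
class-centered samples) is singular.  CLDA operates entirely in its null
space:

1. **Range basis.**  The non-zero eigenpairs (λₖ, vₖ) of the M×M Gram
   matrix AᵀA give Q = [Avₖ/√λₖ], an orthonormal basis of range(S_W).
   The d×d scatter is never formed; all eigenanalysis is on M×M or C×C
   matrices.
2. **Common vectors.**  x_comⁱ = x − QQᵀx for one representative per class
   (the first sample in input order).  The choice is provably irrelevant —
   within-class differences lie in range(S_W) — and the test suite asserts
   the invariance to 1e-8 rather than assuming it.
3. **Discriminant directions.**  The scatter of the centered common vectors
   (rank ≤ C − 1) is eigendecomposed via its C×C Gram matrix; the non-null
   eigenvectors form W.  W ⊥ Q by construction, so every training sample
   projects exactly onto its class template Ωᵢ = Wᵀx_comⁱ, and the
   nearest-Ω classifier has zero training error whenever the common vectors
   are pairwise distinct.

**Numerical choices.**  Eigenvalues of a Gram matrix G (size m) below
m·ε·λ_max are treated as zero (standard numerical-rank tolerance; exposed
as `rank_tol`).  Eigenvector signs are fixed by making each column's
largest-magnitude entry positive, so Ω values and plots are reproducible.
Classes whose common vectors coincide within 1e-8·max‖x_com‖ raise a
`DegenerateDataError` naming the pair — the failure mode in which the null
space carries no class information.  The regime guard d > M − C raises a
`RegimeError` (counting duplicated bootstrap rows as rows, which is
conservative).

S_B and S_T are provided as documented utilities; S_T is unused by CLDA
itself.

## PCA + LDA baseline

PCA on the centered training matrix (thin SVD), then Fisher LDA in the
k-dimensional score space by the generalized eigenproblem S_B w = λ S_W w
(`scipy.linalg.eigh`), keeping at most C − 1 directions; classification is
by nearest projected class centroid.

* `n_components="auto"` keeps the smallest k explaining ≥ 99% of the
  training variance, capped at M − C (and at the numerical rank).  The
  retention rule for the original study is unreported; 99% is a common
  chemometrics default and is exposed as `var_target`.
* If S_W in PCA space is numerically singular it is ridge-stabilized by
  1e-10·trace(S_W)/k on the diagonal; exact singularity (zero trace) is an
  error advising a smaller k.

## AdaBoost-CLDA

AdaBoost.M1 with CLDA + nearest-Ω as the weak learner.  Per round t:

1. normalize weights to the distribution Pₜ;
2. draw n samples **with replacement** from Pₜ (the round's training
   subset) — a draw must contain every class; after 10 failed redraws the
   missing classes' highest-weight samples are appended;
3. fit CLDA on the subset; the weak hypothesis hₜ is nearest-Ω in that
   round's subspace;
4. εₜ = Σ Pₜ(i)·1[yᵢ ≠ hₜ(xᵢ)] over the **full** training set (this is
   required for the weight update to touch every sample);
5. stop if εₜ = 0 or εₜ ≥ ½; otherwise αₜ = ½ln[(1−εₜ)/εₜ];
6. multiply weights by e^{±αₜ} (up for mistakes), which provably makes the
   misclassified mass equal ½ after the next normalization — asserted
   exactly in the tests, together with the AdaBoost.M1 training-error bound
   ∏ₜ 2√(εₜ(1−εₜ)).

Design points:

* **Resampling, not weighted scatter.**  CLDA has no per-sample-weight
  formulation, and fitting on the full set would give εₜ = 0 every round
  (exact training separability), making boosting vacuous.  Weighted
  bootstrap resampling is the standard remedy; a weighted-scatter variant
  is a possible extension.
* **εₜ = 0 handling.**  A perfect round is retained with α capped at
  ½ln[(1−ε_min)/ε_min], ε_min = 1/(2n), then the loop stops; discarding a
  perfect classifier would be pathological, and the cap avoids an infinite
  vote.
* **εₜ = ½ exactly** terminates without retaining the round (its α would
  be 0).  A degenerate *first* round (ε₁ ≥ ½) is a loud `FitError`.
* **T = 10 default**: the ensemble's staged accuracy flattens by ten rounds
  on this problem family.
* Prediction is argmaxᵧ Σₜ αₜ·1[hₜ(x) = y]; ties go to the lowest class
  index.  `staged_accuracy` reports the truncated-vote accuracy per round.
* When a back-end classifier (KNN/naive Bayes) is requested *with* the
  boosted extractor, each round trains that classifier on the round's
  projected full training set and the rounds vote with the same αₜ.  The
  composition mechanism for back-end classifiers is not prescribed by the
  construction; this per-round vote is this package's choice and keeps the
  α bookkeeping meaningful.

## Preprocessing

* **Savitzky–Golay** (scipy `savgol_filter`, `mode="interp"`): default
  window 11, order 2, derivative 0 — common NIR smoothing practice; edge
  polynomials preserve all d channels.  With order = window−1 the filter is
  the identity (interpolating fit).
* **MSC**: per-spectrum OLS regression x ≈ a·ref + b, output (x−b)/a.
  `reference="mean"` uses the mean of the spectra seen at fit time; in
  `apply_chain` that is always the *training* set, frozen for test
  transformation (no leakage).  A constant reference, or |a| < 1e-12,
  is a degeneracy error.
* **SNV**: per-spectrum standardization with the sample (d−1) divisor —
  stated so the worked examples are exact.  Idempotent; invariant to
  per-spectrum positive affine distortion.
* Combinations are ordered lists applied left-to-right; "MSC + SG" means
  MSC then SG (the natural reading of the combination labels, noted as an
  assumption).

## Stratified split

Per class: shuffle (seeded generator), take floor(n·a/(a+b)) for training,
remainder to test — the conservative rounding favours the test set.  The
2:1 split of 4×60 samples gives the 40/20 per-class design.  Whether the
original experiment split randomly or sequentially is unknown; the
seed-controlled random split is this package's convention.

## Synthetic generator

Spectra are a per-class mixture of Gaussian bands on a sloped baseline with
per-spectrum scatter and channel noise (see `synthetic.py`'s docstring for
the formula).  Defaults reproduce the study conditions: 4 classes × 60
samples, 228 channels over 5894.5–11111 cm⁻¹, shared prominent bands at
6993 and 8475 cm⁻¹ (plus two weaker flanking bands), class differences
expressed through band *amplitudes* only.  `class_separation` scales the
amplitude differences around their across-class mean: 0 makes all classes
identically distributed.

Chosen default magnitudes (absorbance units): baseline offset 0.25 with a
shallow positive slope; band amplitudes 0.25–0.80; scatter σ_a = 0.05,
σ_b = 0.02; channel noise σ = 0.005 — plausible for a fruit scanned on a
portable instrument.  The axis is uniform in wavenumber, a simplification
(real instrument gridding is unknown and no algorithm reads the axis).

**Presets** name the three regimes the test suite reasons about:

| preset | separation | noise σ | scatter (σ_a, σ_b) | regime |
|---|---|---|---|---|
| `separable` | 2.0 | 0.002 | (0.01, 0.005) | CLDA alone is perfect |
| `overlapping` | 0.18 | 0.008 | (0.10, 0.04) | CLDA imperfect; boosting helps |
| `scatter_heavy` | 1.0 | 0.005 | (0.30, 0.15) | MSC/SNV visibly correct |

The `overlapping` parameters were calibrated once so that the preset
realizes its defining regime — a single CLDA subspace below 100% with the
boosted ensemble above both single-subspace methods — and then frozen; the
multiplicative scatter is the ingredient that degrades single-subspace
methods relative to the ensemble.

**What passing tests do and do not show.**  The generator has independent
Gaussian channel noise, exactly Gaussian bands and a rank-one scatter
model; real NIR spectra have correlated noise, asymmetric overtone bands
and richer within-class covariance.  Results on these fixtures validate
the *algorithms* (identities, orderings, determinism), not field
performance on any real commodity.

## Evaluation

Accuracy = trace/total of the confusion matrix (rows = truth, columns =
predicted, classes in lexicographic label order).  KNN tie-breaks: vote
count, then summed inverse distance, then lowest class index — stated
because extracted CLDA features produce exact distance ties.  Gaussian
naive Bayes floors per-class variances at 1e-9·(max variance) because
within-class CLDA features are exactly constant; posteriors are computed in
the log domain.

## Problem sizes

Test-suite and acceptance computations use the study-scale design
(240 × 228, 160 training samples) with 20-seed replications for stochastic
claims and 50 seeds for the chance-floor check; small randomized instances
(d ≤ 20, M ≤ 12) are used where a directly formed d×d scatter serves as
the oracle.

## Known limitations

* No kernelized/regularized CLDA, no weighted-scatter boosting variant,
  no SAMME-style multiclass boosting.
* `read_matrix` handles delimited text only (no instrument-native SPA/OPUS
  or JCAMP-DX formats); no spectral resampling or interpolation.
* PCA+LDA's variance-retention rule materially affects its accuracy (the
  worked example shows a seed where smoothing makes 99%-variance retention
  counterproductive); the baseline is faithful but its headline numbers
  depend on that unreported choice.
* Model archives are NumPy `.npz` files, not a portable interchange format.
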