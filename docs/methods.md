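# Methods

## Problem and model

The package predicts whether two proteins interact, using only sequence
information. Interaction is treated as a binary classification problem over
protein *pairs*; each protein contributes an evolutionary profile (PSSM) and
the pair is represented by a fixed-length feature vector. The model chain is

PSSM (L×20) → truncated-SVD descriptor (20·r) → pair concatenation (40·r)
→ centered PCA (k dims) → RVM classifier → probability of interaction,

evaluated by stratified five-fold cross-validation.

## Low-rank PSSM descriptor

A PSSM is parsed from the modern `psiblast -out_ascii_pssm` dialect (40
numeric columns per row; the first 20, the log-odds block, are used — the
weighted-percentage block is ignored). Scores are kept as parsed; no
rescaling is applied at parse time. Parsed integers outside [−32, 32] are
rejected as corrupt.

The profile is transposed to a 20×L matrix N (amino acids × positions) so
that the left factors live in the fixed 20-dimensional amino-acid space;
this is the only orientation under which the descriptor length is
independent of sequence length. The best rank-r Frobenius approximation is
the truncated SVD N* = U₁Σ₁V₁ᵀ, with residual ‖N−N*‖_F =
√(σ²_{r+1}+…+σ²_m). The descriptor is U₁Σ₁^½ flattened row-wise; its
squared norm equals σ₁+…+σ_r.

Numerical choices:

- **Sign convention.** SVD factors are sign-ambiguous; each column of U₁ is
  flipped (with its V₁ column) so its largest-magnitude entry is positive,
  ties broken at the earliest index. Descriptors are therefore bit-identical
  across runs and linear-algebra backends.
- **Repeated singular values.** If σ_r = σ_{r+1} the optimum is not unique;
  the backend's subspace is kept and a warning is logged.
- **Degenerate input.** An all-zero PSSM maps to the all-zero descriptor
  (valid, not an error); L < r is an error.
- **Default rank r = 5** (100 values per protein, 200 per pair), exposed as
  a parameter; the package makes no optimality claim for any particular r.

Pairs are emitted in the order listed. Because concatenation is not
symmetric in (A, B), an opt-in `augment_reversed` flag additionally emits
every training pair in both orders.

## PCA

Centered PCA on the pair vectors, no per-feature rescaling (descriptor
coordinates share a common scale: singular-vector entries × √σ). The
retained dimension is the smallest k whose cumulative explained-variance
ratio reaches `variance_target` (default 0.95), or an explicit
`n_components`; the choice is echoed in the run log. PCA is applied to pair
vectors (not per-protein descriptors) so the classifier sees the same space
the features are defined in.

At small sample sizes (tens of pairs) the 0.95 target retains most of the
training directions; test rows whose variation lies outside the training
subspace are shrunk toward the mean on projection, which can mis-calibrate
the decision threshold even when ranking (AUC) is perfect. At the package's
standard benchmark size (400 pairs) this effect is negligible; for very
small studies a small fixed `n_components` is the more stable choice.

## Relevance vector machine

Weights of the kernel expansion f(x) = w₀ + Σⱼ wⱼK(x, xⱼ) carry independent
Gaussian priors 𝒩(0, αᵢ⁻¹). Regression mode implements the Gaussian-noise
evidence updates literally:

Σ = (σ⁻²ΦᵀΦ + A)⁻¹, μ = σ⁻²ΣΦᵀt, γᵢ = 1 − αᵢΣᵢᵢ,
αᵢ ← γᵢ/μᵢ², σ² ← ‖t − Φμ‖²/(N − Σγᵢ),

iterated until max|Δ log α| < tol (default 10⁻³) or `max_iter` (default
1000). The binary task itself cannot use a Gaussian likelihood — it must
produce probabilities in (0, 1) — so classification mode replaces it with a
Bernoulli likelihood through the logistic sigmoid: an IRLS (Newton) inner
loop with backtracking finds the posterior mode, the Laplace covariance is
Σ = (ΦᵀBΦ + A)⁻¹ with B the sigmoid-derivative diagonal, and the outer α
update is unchanged. Both modes are fully deterministic.

- **Kernel.** RBF K(x,y) = exp(−γ‖x−y‖²); the sparse Bayesian framework is
  not restricted to Mercer kernels, but RBF is the conventional choice for
  this feature space. Default width γ = 1/median pairwise squared distance
  of the training inputs (data-scaled, overridable). A leading bias column
  is included by default and is prunable like any other basis function.
- **Initialisation.** αᵢ = 10⁻⁶ (broad prior); σ² = 0.1·var(t) in
  regression, floored at 10⁻⁶.
- **Pruning.** αᵢ > 10¹² removes basis i permanently; μᵢ = 0 exactly (which
  would divide by zero in γᵢ/μᵢ²) also prunes; if an update would empty the
  model the single best-determined weight is kept.
- **Linear algebra.** All SPD solves use Cholesky with escalating jitter
  (10⁻¹⁰ × mean diagonal, ×10 per retry, 3 retries) because Σ can become
  ill-conditioned after aggressive pruning. σ² is floored at 10⁻¹².
- **Evidence monotonicity.** The Gaussian-mode marginal likelihood
  log p(t|α, σ²) (computed through Ω = σ²I + ΦA⁻¹Φᵀ) is recorded per outer
  iteration and is non-decreasing in the noisy regime. With exactly
  realizable noiseless targets σ² collapses toward its floor and the
  unbounded evidence is no longer a meaningful monotone diagnostic; the
  fitted predictions still reproduce the targets to ~10⁻⁶.
- **Non-convergence** within `max_iter` is reported via
  `FitDiagnostics.converged`, never raised; the returned model is the last
  iterate refitted.
- Prediction returns the posterior-mean latent passed through the sigmoid
  (classification) or the posterior predictive mean (regression); the
  decision label is probability ≥ 0.5.

## Evaluation protocol

Stratified k-fold (default 5) via a seeded shuffled split; per-class fold
sizes differ by at most one. Per fold, PCA and the RVM are fitted on the
training rows only — perturbing a test row can never change a fitted model
(asserted by test). The seven confusion-matrix metrics are computed from
their defining formulas; a metric whose denominator is zero (e.g. PPV when
nothing is predicted positive) is reported as 0 with a logged warning —
this degenerate case is otherwise undefined. Fold aggregation reports the
arithmetic mean and the *sample* standard deviation (ddof = 1) over folds.
ROC curves use the unique-score threshold sweep with trapezoidal AUC, both
per fold and pooled over all test scores; the decision threshold for the
confusion table is fixed at 0.5.

Duplication behavior: duplicating every sample (duplicates grouped into the
same fold) leaves the fold structure, the fitted PCA and the per-fold AUC
exactly unchanged, but not necessarily every thresholded metric — sample
duplication duplicates kernel basis columns and doubles the likelihood
weight, so the evidence-maximised sparse fit is a (slightly) different
model. The tests assert the exact invariances and bound the metric drift.

## Synthetic benchmark generator

The generator emulates the statistical shape of PSI-BLAST profiles and
labeled pair datasets, not evolution or PSI-BLAST itself:

- Profiles are integer matrices in [−10, 13]; the no-signal background is
  Gaussian noise with entry rms 4 (filling most of the score range),
  rounded and clipped. Sequence lengths default to 50–200 (interaction
  benchmarks conventionally drop sub-50-residue sequences).
- The class signal is planted in the left (amino-acid) singular subspace —
  exactly the subspace the descriptor reads. Both members of every
  interacting pair are planted on one class basis drawn once per dataset,
  with a fixed strictly-decreasing spectrum so descriptor column order and
  signs are stable; each non-interacting protein gets its own independent
  basis at the same amplitude. The two classes therefore differ only in
  subspace coherence, not in scale.
- `separation` is the planted component's entry rms in score units:
  0 gives a label-independent null dataset; the standard benchmark value 8
  (twice the noise rms) gives a nearly separable problem.
- Everything is determined by a single seed; fixture files (FASTA with
  random sequences of matching lengths, per-protein PSSMs, pair TSV) can be
  materialized for end-to-end tests. Because the signal amplitude shares
  the clipped integer range with the noise, very large `separation` values
  saturate the score range and *degrade* the planted structure; subspace
  recovery is cleanest for amplitudes ≲ 4.

What passing these tests shows — and does not show. The synthetic classes
are defined by exactly the low-rank structure the descriptor extracts, so
the benchmarks probe the pipeline's mechanics (feature extraction fidelity,
leakage-free evaluation, calibration, sparsity), not biological validity.
Real interaction datasets carry signal of unknown form; headline numbers on
planted data say nothing about accuracy on real proteomes.

## Problem sizes and determinism checks

The standard benchmark is 400 pairs (200/200), chosen so that five-fold CV
leaves 320 training pairs per fold — large enough for stable PCA and
calibrated RVM probabilities. The permutation-null check averages CV
accuracy over 8 label permutations: under random labels a flexible
classifier overfits clustered features, scattering single-permutation
accuracy around chance (sd ≈ 0.04 at this size, slightly below 0.5 on
average), so a multi-permutation mean is the standard stable estimator.

## Known limitations

- The psiblast wrapper shells out to the external binary; profile quality
  (and hence everything downstream) depends on the search database used.
- Only the regression-mode evidence is guaranteed monotone; the Laplace
  evidence trace in classification mode is diagnostic only.
- Sequential (fast marginal likelihood) RVM training is not implemented;
  fits are O(M³) per outer iteration before pruning shrinks M.
- The pair representation is order-dependent; use `augment_reversed` when
  the pair list's orientation is arbitrary.
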