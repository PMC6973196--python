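# Methods

## Model overview

`lgpsvm` classifies expression profiles with a one-vs-one multiclass
soft-margin SVM whose kernel is either one of the three standard kernels
(linear, polynomial `(η(x·x′)+δ)^d`, Gaussian `exp(−‖x−x′‖²/2σ²)`) or the
hybrid linear–Gaussian–polynomial (LGP) kernel

    K(x, x′) = β₁·(x·x′) + β₂·exp(−β₃·(η(x·x′)+δ)^d / (2σ²)),

with mixing weights constrained to the simplex β₁+β₂+β₃ = 1, βᵢ ∈ [0, 1].
With β = (1, 0, 0) the kernel reduces exactly to the linear kernel; with
β₃ = 0 the exponential term degenerates to a constant. The Gaussian
bandwidth is stored as σ and interchangeably as the precision
γ = 1/(2σ²).

The full experiment is: min-max normalize each gene to [0, 1] → random
stratified train/test split → fix a stratified 5-fold plan on the training
set → particle swarm search over the kernel's parameter space, scoring each
candidate by 5-fold cross-validated accuracy with per-fold PCA → refit PCA
on the whole training set, train the final SVM with the best parameters →
score the held-out test set (accuracy, macro F-score, G-mean).

## Assumptions and key contracts

- **Per-fold PCA (leakage freedom).** Within cross-validation, the PCA
  means, spectrum and loadings for fold j are computed from the other four
  folds only; fold j is centered with the calibration means and projected
  onto the calibration loadings. Held-out rows can be perturbed arbitrarily
  without changing anything fitted on the calibration side (tested).
  The retained component count may differ across folds and between CV and
  the final model; that is inherent to the procedure and is reported, not
  unified.
- **Component selection.** k is the smallest number of leading components
  whose cumulative proportion of variance reaches the threshold (default
  0.95, configurable). In the genes ≫ samples regime the N×N covariance
  eigenproblem is computed via the thin SVD of the centered data matrix —
  mathematically identical (eigenvalues are squared singular values over
  M−1) and tractable for N up to ~12 600. Eigenvector signs are fixed by
  making each loading column's largest-magnitude entry positive; near-equal
  eigenvalues keep their SVD order (stable).
- **Mercer validity is checked, not assumed.** The LGP kernel's Taylor
  expansion in powers of the polynomial kernel has alternating signs, so
  positive semidefiniteness does not follow from closure rules for kernel
  sums/products and indeed fails for some admissible parameters: the
  documented counterexample β = (0.05, 0.9, 0.05), η = 8, δ = 0, d = 2,
  σ = 2^−1/2 on the points (1,0), (0,1) yields a Gram matrix with minimum
  eigenvalue ≈ −0.81. The pipeline therefore validates each final training
  Gram matrix spectrally: a warning by default (libsvm tolerates mildly
  indefinite precomputed kernels), an error under `strict_psd`.
- **Normalization timing.** Default `global` mode normalizes before
  splitting (matching the order of the original procedure); a
  `train_fitted` mode fits min/max on the training rows only and clips
  held-out values into [0, 1], for users who prefer strictly leak-free
  scaling. Constant genes map to 0 rather than NaN.

## Tunable parameters

| Parameter | Meaning | Search range / default |
|---|---|---|
| C | soft-margin penalty | log₂C ∈ [−5, 15] |
| β₁, β₂, β₃ | LGP mixing weights | simplex, each ∈ [0, 1] |
| γ = 1/(2σ²) | Gaussian precision | log₂γ ∈ [−15, 3] |
| η | polynomial scale | log₂η ∈ [−15, 3] |
| δ | polynomial offset | [0, 5] |
| d | polynomial degree | integer {2, 3, 4, 5} |
| k folds | cross-validation folds | 5 |
| PPV threshold | cumulative variance cutoff | 0.95 |
| swarm size | particles | 10 × D (D = 1/2/4/8 for L/G/P/LGP) |
| w, c₁, c₂ | inertia, learning factors | 1, 2, 2 |
| iterations | PSO updates | 50 |

## Optimizer details

The swarm uses the canonical update
v ← w·v + c₁r₁(pbest−x) + c₂r₂(gbest−x), x ← x+v, with three choices the
canonical description leaves open:

- **Velocity clamp.** With w = 1 the canonical swarm can diverge, so each
  velocity component is clamped to half the box width; positions are
  clamped to their bounds and the clamped component's velocity zeroed.
- **Simplex handling.** The three β weights are searched as independent
  raw dimensions in [0, 1] and renormalized by their sum at decode time; a
  group whose raw sum collapses below 10⁻⁶ is re-randomized.
- **Encoded-space fitness.** The fitness callable receives the raw
  (encoded) position; the pipeline composes it with the decoder. log₂-scale
  dimensions are exponentiated and the degree rounded to the nearest
  integer at decode.

Fitness is the mean validation accuracy over the pre-fixed folds (a G-mean
variant is available via `fitness_metric="g_mean"`), making the objective
deterministic so personal/global bests are well defined; ties keep the
first-achieved global best. Candidate parameters whose kernel values
overflow double precision (large positive exponents from odd-degree
negative projections) score 0 with a warning, steering the swarm away
without aborting the search. NaN fitness is treated as −∞.

## The multiclass SVM

One binary soft-margin SVM per unordered class pair, each trained on the
pair's sub-block of the precomputed training Gram matrix (the pairwise QPs
are solved by libsvm through scikit-learn's precomputed-kernel interface;
dual box and equality constraints are asserted post-fit). Prediction is
majority voting over the C(C−1)/2 pairwise decisions with ties going to
the lowest class index. Dual coefficients, support indices and biases are
extracted into a plain JSON-serializable model, so re-prediction needs only
cross-Gram columns, not the solver. A calibration fold missing a class
trains only the pairwise models for the classes present (warning); with a
single class left, the fold degenerates to predicting that class.

## Series oracle and numerical validation of the kernel

The exponential term of the LGP kernel admits the Taylor expansion
β₂·Σᵢ (−β₃γ)ⁱ·K_poly^i / i!, which serves as an independent cross-check of
the closed form. Two numerical facts govern its use:

- the truncation remainder after n terms is bounded by |b|ⁿ⁺¹/(n+1)! with
  b = β₃γ(η(x·x′)+δ)^d, so the truncation depth must grow with |b|
  (`series_terms_needed` computes it);
- beyond |b| ≈ 17 the raw alternating sum is destroyed by floating-point
  cancellation (intermediate terms reach e^|b|) even though the series
  converges mathematically. For those magnitudes the oracle evaluates the
  same truncated series at b/2^k with |b/2^k| ≤ 1 — where 30 terms leave a
  remainder below 1/31! — and squares the partial sum k times
  (exp(b) = exp(b/2^k)^(2^k)).

The validation suite draws parameters across the full search ranges (log₂
scale for γ and η, matching how the optimizer samples them) with inputs of
at most unit norm (the post-normalization regime) and checks closed form
against oracle to 10⁻⁸.

## Synthetic data

The generator emulates the microarray regime, not microarray physics: the
first `n_informative` genes carry class structure, the rest are i.i.d.
Gaussian noise, and the matrix is shifted/scaled into a positive
expression-like range (min-max normalization erases the affine map
downstream). Class structure is `linear` (class c shifts informative means
by c·effect·SD with a random sign per gene), `radial` (classes on
concentric shells of radius effect·(1+2c)·SD in the informative subspace —
separable by a local kernel, not by a hyperplane), or `mixed` (half/half).
Defaults — effect size 3 noise-SDs, 20 informative genes, unit noise —
give strongly but not trivially separable classes, the regime in which the
reference cohorts are reported to be classifiable. Stand-ins shaped like
the four classic cohorts (Colon 62×2000×2, AML-ALL 72×7129×2, St. Jude
215×12558×7 with a diffuse "other" class, Lung 203×3312×5) use their
published class counts. Not modeled: probe effects, batch effects, heavy
tails, gene–gene correlation beyond the informative block; a perfect score
on this generator therefore demonstrates the pipeline's correctness and
leakage-freedom, not expected performance on real cohorts.

## Problem sizes in the test and acceptance runs

Unit and acceptance tests run the full pipeline on 60-sample × 200-gene
datasets with demo-sized swarms (6–16 particles, 3–10 iterations) — ample
for strongly separable data, where most of the search space already scores
perfectly, and small enough to keep the suite fast. The defaults (10×D
particles, 50 iterations) are what an actual analysis should use. The
acceptance script reports test counts {17, 17, 60, 58} for the four
reference cohort designs; these are fixed per cohort because no single
rounding rule reproduces all four published percentage rows.

## Known limitations

- The reported experiment uses a single seeded split; repeat-averaging is
  left to the caller (loop over `seed_split`).
- Indefinite Gram matrices are accepted by default; solutions then lack the
  global-optimality guarantee of the convex case.
- No probability calibration, one-vs-rest mode, or class-weighted C.
- The degree is searched as a continuous dimension and rounded at decode,
  which plateaus the objective between integer values.
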