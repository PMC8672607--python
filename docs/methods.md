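# Methods

## Model and training criterion

`pdcr` classifies samples by nearest centroid in a learned
low-dimensional space. The data matrix `X (m × d)` holds autoscaled
log-intensities; the one-hot matrix `Y (m × k)` encodes class
membership. Training solves the convex problem

```
min_{W, μ}  h_δ(Yμ − XW) + (ρ/2) ‖I_k − μ‖_F²   s.t.  ‖W‖₁ ≤ η
```

- The data-fit term asks the projection of every sample, `x_i W`, to
  land near its class centroid `μ_j` (row `j` of the `k × k` matrix
  `μ`). Applied entrywise, the Huber function `h_δ` is quadratic for
  small residuals and linear for large ones, so a few aberrant samples
  cannot dominate the fit the way they do under a squared loss, while
  the criterion stays differentiable at zero (unlike a pure ℓ1 loss,
  which would also force exact interpolation of the training data).
- `‖W‖₁` is the *entrywise* sum of absolute values, not the induced
  matrix norm. The ball constraint is what produces feature selection:
  rows of `W` that do not pay their way are driven exactly to zero,
  and the surviving rows define both the classifier and the feature
  ranking.
- The ridge `(ρ/2)‖I_k − μ‖²` anchors centroids near the identity
  (class j's prototype near the j-th unit vector), breaking the
  homogeneity that would otherwise allow the trivial solution
  `(W, μ) = (0, 0)`.

Prediction projects a (identically preprocessed) sample and takes
`argmin_j ‖μ_j − xW‖₁`; the ℓ1 distance in the projected space matches
the robust spirit of the training loss. Ties go to the lowest class
index, deterministically.

## Optimization

The criterion is "smooth-loss ∘ linear map + separable proximable
terms", the canonical shape for the Chambolle–Pock primal-dual
splitting. With the linear operator `A(W, μ) = Yμ − XW` and dual
variable `Z` in the residual space, one iteration is

```
Z   ← prox_{σ h*}( Z + σ (Y μ̄ − X W̄) )       (entrywise clip(z/(1+σδ), ±1))
W⁺  ← Π_{‖·‖₁ ≤ η}( W + τ Xᵀ Z )              (exact sort-based projection)
μ⁺  ← (μ − τ Yᵀ Z + τ ρ I_k) / (1 + τ ρ)      (closed form)
(W̄, μ̄) ← 2 (W⁺, μ⁺) − (W, μ)                 (extrapolation)
```

Choices that were genuinely open and how they were fixed:

- **Step sizes.** `σ = τ = 0.99 / ‖A‖` with `‖A‖` estimated by power
  iteration on `AᵀA` (deterministic seed), satisfying the convergence
  condition `στ‖A‖² ≤ 1`. Both steps are overridable.
- **Initialization.** `W = 0`, `μ = I_k`, `Z = 0`. The solver contains
  no randomness: refits are bit-identical.
- **Stopping.** Relative change of `(W, μ)` below `tol` (default
  1e-6), or `max_iter` (default 2000). The objective trace is recorded
  for diagnostics but not used to stop: primal-dual objectives are not
  monotone.
- **Feasibility.** Every iterate is inside the ℓ1 ball by
  construction; the per-iterate `‖W‖₁` trace is kept so this is
  checkable after the fact.
- **ℓ2 variant.** `loss="squared_l2"` replaces the Huber term by
  `½‖Yμ − XW‖²` (dual prox `z ↦ z/(1+σ)`), giving the non-robust
  reference model used in the outlier comparison.
- **Projection.** Exact O(n log n) simplex-style projection; threshold
  ties resolved by the standard cumulative-sum rule. Verified against
  a bisection oracle and dense threshold grids.

Default parameters: `δ = 0.3`, `ρ = 1.0` (fixed once, not tuned per
dataset), `η = 5.0`. Only `η` is meant to be tuned: it directly sets
the size of the selected feature set, and the right value depends on
the scale and redundancy of the data.

## Preprocessing

Raw tables pass through prevalence filtering (keep features detected —
intensity > 0 — in at least a fraction `min_fraction` of samples,
default 0.1, boundary kept), log transform
(`x ↦ log10(x + pseudocount)`), and autoscaling (per-feature mean
centering and division by the sample standard deviation; zero-variance
features get scale 1 with a warning). All parameters are fitted on
training partitions only and replayed on held-out data; the
cross-validation code never lets a test fold influence the transform
or the solver.

**Pseudocount for tables with true zeros.** With intensities spanning
10³–10⁶, a pseudocount of 1 maps non-detected entries (zeros) to ~0 on
the log scale — three to six decades below real signal — turning each
dropout into an extreme low outlier that drowns class differences.
On data with true zeros we therefore recommend, and the synthetic
protocol uses, a pseudocount at the scale of the intensity
distribution: `suggest_pseudocount` returns the median positive
intensity, playing the same role as the half-minimum imputation common
in metabolomics pipelines. The library default remains the
conventional 1 (harmless when the table has no zeros); the choice is
logged by the CLI.

## Confidence score and rejection

For two classes `ρ(x) = (d₁ − d₂)/(d₁ + d₂) ∈ [−1, 1]`; the sign is
consistent with the argmin rule (negative = class 1) and the score is
emitted signed. For `k > 2`, `ρ(x) = 1 − k·min(d)/Σd ∈ [0, 1]`; at
`k = 2` its value equals |binary CSP| exactly. Rejection uses strict
inequalities: a sample is rejected iff |ρ(x)| < ε (binary) or
ρ(x) < ε (multi-class), so ε = 0 rejects nothing and a score exactly
at the threshold is classified. The multi-class rejection rule is this
package's extension; only the binary rule has an external reference.

The rejection curve reports, per ε, `FDR(ε)` = misclassified among
accepted / **all** samples — a misclassification load, kept with this
denominator deliberately — alongside the conventional conditional rate
(`fdr_conditional`, divided by the accepted count) and the rejection
rate `RRS(ε)`. FDR is non-increasing and RRS non-decreasing in ε by
construction.

## Evaluation protocol

Stratified 4-fold cross-validation, repeated over shuffle seeds
(default {0, 1, 2}), with the full pipeline refit per training fold.
Stratification is used because fold-level class absence would break
centroid fitting. Accuracy is exact-match on held-out folds; AUC is
the Mann–Whitney statistic (midranks, ties ½) of the signed binary
CSP, the model's only continuous output.

## Synthetic data generator

The generator emulates the structure of two-class untargeted LC-MS
feature tables at desk scale:

| parameter | default | meaning |
|---|---|---|
| `m` | 100 | samples, balanced classes, shuffled order |
| `d` | 1000 | features |
| `s` | 10 | discriminative base metabolites |
| `adducts_per_base` | 3 | correlated copies per base (adducts/isotopologues) |
| `log2_fold_change` | 1.6 | class-2 shift of each base, planted on the log scale |
| `base_log10_mean_range` | [3, 6] | per-feature log10 abundance means (uniform) |
| `feature_sd_log10` | 0.3 | per-feature biological+technical log-noise |
| `adduct_jitter_sd` | 0.05 | extra noise decorrelating adduct copies (r ≈ 0.97) |
| `dropout_prob` | 0.1 | per-entry probability of a detection zero |
| `outlier_sample_frac` / `outlier_scale` | 0 / 5 | fraction of samples with log-noise sd inflated ×scale |

Intensities are lognormal (multiplicative noise becomes additive after
the log transform, which is the rationale for logging in the first
place); fold changes are planted on the log scale at a magnitude
comparable to real discriminative metabolites; adduct blocks share one
per-sample latent signal plus a fixed offset and small jitter;
dropout produces exact zeros so the prevalence filter and the
pseudocount logic are genuinely exercised; outlier samples exist
specifically to probe the Huber-vs-ℓ2 robustness claim.

What the generator does **not** model: realistic m/z values or isotope
physics, retention-time structure, intensity-dependent (left-censored)
dropout, batch effects, or class imbalance. Passing the synthetic
suite therefore shows the machinery is correct and the method behaves
as designed under this noise model — not that a given real dataset
will reach the same accuracies.

## Study conditions used by the test suite and acceptance script

All problem sizes were chosen so the full protocol runs in minutes on
one CPU:

- **Recovery:** generator defaults (m=100, d=1000, s=10, 3 adducts,
  FC 1.6), 10 generator seeds, `η = 5`, pseudocount =
  `suggest_pseudocount`, medians reported. `η = 5` is the tuned value
  for this regime, found by the usual practice of tuning the single
  free parameter; it keeps on the order of a hundred features.
- **Null control:** m=100, d=200, labels permuted, 20 seeds, pooled
  accuracy compared to the 95% binomial band around the 0.5 majority
  rate.
- **Robustness:** m=100, d=200, 10% outlier samples at scale 5,
  20 seeds, median CV accuracy of Huber vs squared-ℓ2. Note: at
  `δ = 0.3` the fitted residuals typically stay inside the quadratic
  branch (the constrained model can nearly interpolate), so the two
  losses often coincide and the comparison resolves as a tie rather
  than a strict gap; the robustness guarantee is "no worse", which is
  what the suite asserts.
- **Solver optimality:** tiny random instances (m ≤ 10, d ≤ 6)
  against a long-run projected-gradient reference built from
  independent primitives; agreement to 1e-4 in objective value.

## Known limitations

- Sparse ℓ1 selection keeps one representative of a group of
  near-duplicate features when the signal is strong; the full adduct
  block is recovered only in noisier regimes where averaging over
  copies pays. Rankings across CV folds (`per_fold_top_features`)
  are the practical stability check.
- The CSP is a geometric confidence, not a calibrated probability.
- Test tables must contain exactly the training features (any order);
  unseen or missing features are an error, never silently dropped —
  silent feature-alignment bugs corrupt `xW` invisibly.
- Multi-class (k > 2) support is implemented and tested at the
  algebra level, but the evaluation protocol (AUC, rejection curve)
  is binary.
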