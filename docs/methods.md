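# Methods

## Model

`slrr` decomposes an expression matrix as **Y = XB + L + e**, with
**X** ∈ ℝ^{n×p} the methylation predictor matrix, **B** ∈ ℝ^{p×q}
sparse, **L** ∈ ℝ^{n×q} low-rank, and e i.i.d. Gaussian noise.  The two
structural assumptions are:

* each gene's expression is affected by only a small number of CpG
  sites, so B is sparse;
* the non-methylation drivers of expression (subtype, batch, sequence
  changes — collectively "expression heterogeneity") act through a few
  latent factors, so L is low-rank.  Any rank-K matrix factors as
  L = WH, which makes the formulation an unconstrained cousin of the
  linear mixed model y = Xβ + Zμ + e with the random-effect design
  absorbed into L.

The hard constraints rank(L) ≤ r and ‖B‖₁ ≤ t are relaxed to their
convex penalized form

f(B, L) = ½‖Y − XB − L‖²_F + ρ‖B‖₁ + λ‖L‖₊,

which is jointly convex in (B, L).  The noise variance σ² is not
estimated; the residual Y − XB − L plays the role of e.

## Algorithm

Block coordinate descent from B = 0, L = 0, L-block first:

1. **L-step.**  For fixed B, the minimiser is the nuclear-norm proximal
   operator (singular value thresholding): SVD the residual
   W = Y − XB = U diag(d) Vᵀ and set L = U diag((dᵢ − λ)₊) Vᵀ.  The
   step is exact, and the nuclear norm of the update equals the sum of
   the thresholded singular values, which the solver reuses when
   evaluating the objective.
2. **B-step.**  For fixed L, the problem separates into q independent
   Lasso regressions of the columns of Y − L on X.  Each is solved by
   cyclic coordinate descent with exact univariate soft-threshold
   updates on the Gram form (X'X is computed once per fit and shared by
   all columns; the inner kernel is JIT-compiled with numba).  Columns
   warm-start from the previous outer iteration, and their solutions
   are independent of the order in which they are solved.

Both steps minimise their block exactly, so the objective is
non-increasing; the solver treats an increase beyond
1e-8·max(1, |f|) as an internal error rather than a warning, because it
can only arise from a bug.  Iteration stops when the relative objective
change falls below `tol` or at `max_iter`.

Centering is on by default: the columns of Y and X are mean-centered
before fitting and the offsets stored in the result.  The model carries
no explicit intercept; centering absorbs it.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| ρ (`rho`) | user-supplied | l1 weight; ρ ≥ max\|X'Y\| forces B = 0 |
| λ (`lam`) | user-supplied | nuclear-norm weight; λ ≥ σ₁(Y − XB) forces L = 0 |
| `max_iter` | 100 | outer iterations |
| `tol` | 1e-6 | relative objective-change stopping rule |
| `cd_tol` / `cd_max_iter` | 1e-7 / 1000 | per-column coordinate-descent stopping rule (max absolute coefficient update per sweep) |
| `rank_tol` | 1e-8 | singular values below `rank_tol`·max(σ₁, 1) do not count toward the numerical rank |
| `center` | true | column-center Y and X |

ρ and λ have no principled closed-form choice here, so the package
ships a convenience selector (`select_penalties`): a grid
ρ ∈ ρ_max·{1, ½, ¼, …} with ρ_max = max|X'Y|, λ ∈ σ₁(Y)·{½, ¼, …},
scored by the BIC-like quantity nq·log(RSS/nq) + log(nq)·df with
df = nnz(B) + r(n + q − r), r = rank(L).  The selector is plumbing, not
part of the model; on the simulated regimes below it reliably recovers
the generating rank.  Users with domain knowledge should set ρ, λ
directly.

No statistical significance test is attached to B; ranking associations
by |B| is the supported interface, and `top_associations` breaks ties
lexicographically by (site_id, gene_id) so output is deterministic.

## Synthetic-data generator

`generate_dataset` draws X with i.i.d. Bernoulli(0.25) entries (binary
methylated / unmethylated states), plants exactly round(0.02·p·q)
standard-Gaussian coefficients at uniformly chosen positions of B,
builds the confounder as L = √τ·HZ with H (n×K) and Z (K×q) standard
Gaussian — so each column of L is N(0, τHH') and rank(L) ≤ K — and adds
N(0, σₑ²) noise.  Per-entry variance of L is τK.  Defaults: n = 200,
p = 100, q = 100, K = 3, τ = 1, σₑ = 1.  A single seed drives four
independent substreams (X, B, factors, noise), so perturbing one
component leaves the others bitwise unchanged.

What the generator deliberately does **not** emulate: beta-values in
(0,1) with their characteristic bimodality (X is binary), correlation
between neighbouring CpGs, count-distributed expression, or
mean–variance coupling.  Passing recovery tests therefore demonstrates
that the estimator separates sparse effects from low-rank confounding —
not that it is robust to every artefact of array or sequencing data.

Support recovery is scored by ROC over all p·q entries with |B̂ᵢⱼ| as
the score and B_true ≠ 0 as the label (tied scores collapse to one
threshold step; AUROC by trapezoid).  The test suite exercises an easy
regime (n=200, p=50, q=50, K=2, τ=1, σₑ=0.5; mean AUROC ≈ 0.88 over 5
replicates with selector-chosen penalties) and a p ≫ n, q regime
(n=100, p=300, q=50) where recovery measurably degrades — the expected
overfitting direction when predictors outnumber samples.  These sizes
keep a full-suite run to a few seconds per fit while leaving the
contrast between regimes unambiguous.

## Preprocessing decisions

* **Missingness**: a CpG site is dropped when missing in more than 70%
  of samples; survivors are mean-imputed per site.  (Imputation method
  is a package choice; nothing downstream depends on it strongly.)  An
  optional chromosome drop-list exists in the CLI but is off by
  default.
* **Promoter window**: sites with TSS offset in the closed interval
  [−2000, +500] bp are kept (upstream negative).  Unannotated sites
  are dropped with a logged count.
* **Clinical**: records with missing follow-up or follow-up strictly
  below 30 days are removed; exactly 30 days survives.
* **Sample intersection**: both matrices are restricted to the sorted
  common sample IDs (optionally intersected with the clinical table);
  outputs share the identical row order.
* **DE gene selection**: per-gene two-sided Wilcoxon rank-sum
  (asymptotic) tumor vs normal, Benjamini–Hochberg adjustment, keep
  genes with adjusted p < 0.05 and |log2 fold change of group means,
  pseudo-count 1| ≥ 1.  The test, threshold and fold-change cutoff are
  package choices; α ≥ 1 disables the significance filter (adjusted
  p-values can equal 1 exactly).

All filters are idempotent and only remove or impute.

## Subtyping from the low-rank component

A converged L defines sample subtypes: k is read off as the numerical
rank of L (floored at 1), samples are embedded as the top-k left
singular vectors scaled by their singular values, and k-means (20
restarts, fixed seed) assigns labels.  The map from a low-rank matrix
to discrete groups is genuinely under-determined; k-means on the scaled
row space is the standard operationalisation of "samples sharing the
same rank structure form a group", and tests verify exact recovery on
constructed block geometry plus permutation equivariance.

Subtype-associated CpGs are called by a one-vs-rest two-sided rank-sum
test per (site, cluster), flagging sites significant (raw p below an
extreme threshold, default 1e-10) in more than `min_clusters` clusters
(default 2).  No multiple-testing correction is applied at that
threshold — it is already far beyond any plausible family-wise bound —
but a BH-adjusted significance count is emitted alongside.  A caveat
discovered while validating: under one-vs-rest location testing, only
clusters at the extremes of the pooled beta distribution can reach
arbitrarily small p; an interior cluster's rank-sum statistic saturates
at a modest effect size, so flagging a site in ≥3 clusters requires
either distinct per-cluster levels or large per-cluster n.  The test
suite uses 4 clusters × 200 samples at distinct levels.

## Numerical choices and degenerate inputs

* Dense LAPACK SVD throughout (desk-scale matrices; no randomized SVD).
* λ = 0 makes the L-step the identity; ρ = 0 makes the B-step ordinary
  least squares by coordinate descent.  Both limits are tested against
  the standalone component solvers to 1e-6.
* An all-zero predictor column has its coefficient pinned to 0.
* Matrix TSVs are written with 17-significant-digit floats and read
  with round-trip float parsing, so write→read reconstructs B and L to
  better than 1e-12 (pandas' default fast parser is 1 ulp lossy).
* K-means and every other stochastic step takes an explicit seed; the
  alternating solver itself is deterministic.

## Known limitations

* No inference (p-values, confidence intervals) on B.
* ρ, λ selection is heuristic; cross-validation is not provided.
* The solver materialises dense n×q and p×q matrices; it targets
  cohort-scale (hundreds of samples, thousands of features) problems,
  not genome-wide site sets without prior filtering.
* The clustering count k inherits the sensitivity of the numerical rank
  to λ: heavier nuclear-norm penalties give fewer subtypes.
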