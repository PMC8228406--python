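# slrr — sparse-plus-low-rank regression of expression on methylation

`slrr` links DNA methylation to gene expression in heterogeneous tumor
cohorts.  Promoter CpG methylation can silence genes, but expression is
also driven by hidden factors — molecular subtype, batch, sequence
changes — that confound naive site-by-gene association testing.  `slrr`
models both at once: given a methylation beta-value matrix
**X** (n samples × p CpG sites) and an expression matrix
**Y** (n samples × q genes), it solves

```
min_{B,L}  ½‖Y − XB − L‖²_F + ρ‖B‖₁ + λ‖L‖₊
```

where **B** (p × q) is a sparse coefficient matrix carrying the
methylation → expression effects, **L** (n × q) is a low-rank matrix
absorbing expression heterogeneity (‖·‖₊ is the nuclear norm, the convex
surrogate for rank), and ρ, λ control the sparsity of B and the rank of
L.  The solver alternates two exact block minimisations until the
objective stalls:

* **L-step** — singular value thresholding of the residual,
  `L ← S_λ(Y − XB)`, the proximal operator of the nuclear norm;
* **B-step** — q independent Lasso problems, one per gene column of
  `Y − L`, solved by warm-started cyclic coordinate descent.

On top of the solver the package provides the synthetic-data study used
to validate support recovery, preprocessing filters for paired
methylation / expression / clinical data (missingness, promoter windows,
follow-up, sample intersection, differential-expression gene selection),
and post-fit analyses: ranking associations by |B|, clustering samples
on the low-rank component (k = rank(L)), and calling subtype-associated
CpG sites.  It is aimed at epigenomics analysts working with TCGA-style
paired matrices.

## Worked example

```python
import slrr

# 200 samples, 50 CpG sites, 50 genes, 2 hidden factors, 2% true effects
cfg = slrr.SimulationConfig(n=200, p=50, q=50, K=2, tau=1.0, sigma_e=0.5, seed=1)
ds = slrr.generate_dataset(cfg)

rho, lam, _ = slrr.select_penalties(ds.Y, ds.X)   # BIC-like grid search
res = slrr.fit(ds.Y, ds.X, slrr.FitConfig(rho=rho, lam=lam))
print(res.converged, res.n_iter, res.rank, res.B.nnz)

roc = slrr.support_recovery_roc(res.B, ds.B_true)
print(f"support-recovery AUROC = {roc.auroc:.3f}")

top = slrr.top_associations(res.B, top_n=5)
clus = slrr.cluster_samples(res.L, seed=0)
```

This prints:

```
True 5 2 33
support-recovery AUROC = 0.830
```

The fit converged in 5 outer iterations; the selected penalties recover
a rank-2 heterogeneity term — matching the K = 2 hidden factors that
generated the data — and keep 33 non-zero coefficients out of 2500.  An
AUROC of 0.83 means that ranking entries by |B̂ᵢⱼ| places truly causal
site-gene pairs far above null pairs.  The top associations table lists
the strongest effects (here `cg000046 → gene0030`, coefficient 2.04),
and `cluster_samples` groups the 200 samples into k = rank(L) = 2
subtypes (sizes 110 / 90) from the low-rank embedding.

The same pipeline is available from the shell:

```
slrr simulate --n 200 --p 50 --q 50 --k 2 --sigma-e 0.5 --seed 1 --out-dir sim/
slrr fit --meth sim/X.tsv --expr sim/Y.tsv --auto-penalties --out-dir fit/
slrr associations --fit-dir fit/ --top-n 100 --out assoc.tsv
slrr cluster --fit-dir fit/ --meth sim/X.tsv --out labels.tsv
slrr subtype-sites --meth sim/X.tsv --labels labels.tsv --out sites.tsv
```

All matrices travel as TSV (header row of feature IDs, first column of
sample IDs, `NA` for missing); B is written as a sparse triplet table
and every command is byte-for-byte reproducible from its `--seed`.

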