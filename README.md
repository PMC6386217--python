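# hpfactor

Hierarchical Poisson factorization for sparse single-cell RNA-seq count
matrices: de novo discovery of gene expression programs from raw UMI counts,
with no prior normalization, log transform, or variable-gene selection
required before fitting.

## Who this is for

Analysts of droplet- or microwell-based scRNA-seq who want interpretable,
non-negative factors (gene signatures and per-cell program activities)
directly from a molecular count matrix. Unlike PCA/FA-style methods, the
model treats counts as counts — sparsity and over-dispersion fall out of the
generative process rather than being normalized away.

## The model

For a cells × genes matrix `x` of UMI counts with `K` latent factors:

    ξ_i  ~ Gamma(a', b')        per-cell capacity (inverse budget)
    θ_ik ~ Gamma(a, ξ_i)        cell loading on factor k
    η_g  ~ Gamma(c', d')        per-gene capacity (inverse budget)
    β_gk ~ Gamma(c, η_g)        gene loading on factor k
    x_ig ~ Poisson(θ_i · β_g)

Capacities act as Gamma *rates* of the loadings, so a high-capacity value
means a low-output cell or gene; marginally each count is a Gamma-mixed
Poisson, i.e. negative binomial, which matches the over-dispersion of real
UMI data. Defaults `a = c = 0.3`, `a' = c' = 1`; `b'`/`d'` are set from the
data to preserve the variance-to-mean ratio of total molecules per cell and
per gene.

Inference is coordinate-ascent variational inference on a conjugate
augmentation (per-molecule factor assignments), with closed-form Gamma
updates that touch only the non-zero entries: `O(NK + MK + TK)` time and
memory for `T` non-zeros. Cells and genes are then ranked per factor by
**scores** — posterior-mean loading times posterior-mean capacity,
`E[ξ_i|x]·E[θ_ik|x]` and `E[η_g|x]·E[β_gk|x]` — which adjust loadings for
learned transcriptional output.

Also included: held-out benchmarking on 4%/2% non-zero splits against a
rank-K Gaussian baseline, posterior predictive checks on
coefficient-of-variation distributions (two-sample KS), dropout-score
variable-gene selection, a prevalence prefilter, and a synthetic-data module
that samples the generative process exactly.

## Worked example

```python
import numpy as np
from hpfactor import (HyperParams, FitConfig, fit, sample_generative,
                      default_sim_hyper, cell_scores, rank_genes,
                      estimate_inverse_budget_hyperparams)

truth = sample_generative(200, 300, default_sim_hyper(3), seed=0)
X = truth.counts
print(f"{X.n_cells} cells x {X.n_genes} genes, {X.nnz} non-zero entries "
      f"({100 * X.nnz / (X.n_cells * X.n_genes):.1f}% occupied)")
b, d = estimate_inverse_budget_hyperparams(X)
print(f"empirical hyperparameters: b' = {b:.3e}, d' = {d:.3e}")
model = fit(X, HyperParams(K=3), FitConfig(n_trials=2, seed=0))
print(f"converged: {model.converged} after {model.loss_history[-1][0]} sweeps; "
      f"final mean log-likelihood {model.loss_history[-1][1]:.4f}")
print("top genes for factor 0:", rank_genes(model, 0, 5))
cs = cell_scores(model)
print(f"cell-score matrix {cs.shape}, example row: {np.round(cs[0], 3)}")
```

prints

```
200 cells x 300 genes, 12371 non-zero entries (20.6% occupied)
empirical hyperparameters: b' = 1.317e-05, d' = 5.685e-05
converged: True after 200 sweeps; final mean log-likelihood -2.1275
top genes for factor 0: ['gene233', 'gene88', 'gene144', 'gene261', 'gene17']
cell-score matrix (200, 3), example row: [0.238 0.853 0.193]
```

The simulated matrix is ~80% zeros; the fit converges when the monitored
mean Poisson log-likelihood changes by less than 0.001% at two consecutive
10-sweep checkpoints. `rank_genes` lists each factor's signature;
`cell_scores` gives every cell's activity on each program.

The same workflow is available from the shell:

```sh
hpfactor simulate --n-cells 200 --n-genes 300 --k 3 --seed 0 --out-prefix sim
hpfactor prep  --input sim.mtx --genes sim.genes.tsv --out-prefix filtered
hpfactor train --input filtered.mtx --genes filtered.genes.tsv \
               --k 3 --trials 10 --seed 0 --out model.npz
hpfactor score --model model.npz --top-n 50 --out-prefix scores
hpfactor benchmark --input filtered.mtx --genes filtered.genes.tsv \
                   --k 3 --seed 0 --out-prefix bench
```

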