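# Methods

## Model

`hpfactor` fits a hierarchical Gamma–Poisson factorization to a cells ×
genes matrix of molecular (UMI) counts. Each cell `i` has a capacity
`ξ_i ~ Gamma(a', b')` and loadings `θ_ik ~ Gamma(a, ξ_i)` over `K` factors;
each gene `g` has a capacity `η_g ~ Gamma(c', d')` and loadings
`β_gk ~ Gamma(c, η_g)`; the observed count is `x_ig ~ Poisson(θ_i · β_g)`.
Capacities enter as Gamma **rate** parameters of the loadings — they are
inverse budgets: a larger capacity draw shrinks every loading of that cell
or gene, which is how systematic differences in sequencing depth and overall
gene expression are absorbed without any explicit normalization. Because a
Gamma-mixed Poisson is a negative binomial, every marginal count is
over-dispersed, and because UMIs collapse PCR duplicates, the Poisson
observation model for molecules is appropriate at the observation layer.

Cell and gene scores multiply posterior-mean loadings by posterior-mean
capacities (`E[ξ_i|x]·E[θ_ik|x]`, `E[η_g|x]·E[β_gk|x]`), adjusting each
factor association for the learned transcriptional output of its cell or
gene; gene rankings within a factor (the factor's signature) sort by this
score, with ties broken by gene index for determinism.

## Inference

The model is made conditionally conjugate by splitting each count into
per-factor molecule assignments `z_igk ~ Poisson(θ_ik β_gk)` with
`x_ig = Σ_k z_igk`; given the total, the assignments are multinomial with
parameter `φ_ig` proportional to the per-factor rates. The mean-field family
puts independent Gammas on `θ, β, ξ, η` (parameters `γ, λ, κ, τ`) and a
multinomial on each non-zero entry's assignments. Coordinate ascent then has
closed-form updates, applied in a fixed order each sweep:

1. gene block — `λ` shapes (prior shape plus `Σ_i x_ig φ_igk` over non-zero
   entries), `λ` rates (capacity mean plus column sums of `E[θ]`), then `τ`
   rates from the just-updated `λ` means;
2. cell block — the exact mirror for `γ` and `κ`, using the same `φ` and the
   new `λ` means;
3. `φ` recomputed from the updated state (log-space with max-subtraction,
   so extreme parameters cannot overflow).

The capacity shape parameters are constants (`κ_shp = a' + Ka`,
`τ_shp = c' + Kc`) fixed at initialization.

Only the `T` non-zero entries carry `φ` and enter the shape sums, giving
`O(NK + MK + TK)` work per sweep; `φ` is held as a `T × K` block, never as a
dense `N × M × K` tensor. The test suite checks each sweep against exactly
such a dense triple-loop reference.

**Update order on the first sweep.** `φ` is *not* derived from the randomly
initialized `γ/λ` before the first shape updates; the first sweep instead
uses an independent symmetric-Dirichlet draw per non-zero entry
(concentration 1.0 — uniform over the simplex, the least informative
choice). Recomputing `φ` first couples all factors to the same random state
and tends to produce redundant factors with near-identical loadings.

**Hyperparameters.** `a = c = 0.3` (sparsity-favouring) and `a' = c' = 1`.
The capacity rates are set empirically to preserve the variance-to-mean
ratio of total molecules: `b' = a'·E[molecules per cell]/Var[molecules per
cell]`, and `d'` likewise per gene. Totals include implicit zeros; the
variance is the population (denominator `n`) estimator so the procedure is a
deterministic moment match. Zero variance of either total is reported as a
degenerate input naming the axis. Note the capacity hyperpriors are
parameterized by their rates directly — `Gamma(a', b')` — not by a mean
`a'/b'`; converting from the mean convention requires inverting the ratio.

**Initialization.** All variational parameters other than the fixed capacity
shapes start at their prior values times independent uniform multipliers in
`[0.5, 1.5]` (drawn per parameter, not per array). The loadings' prior rate
is the random capacity; it is taken at its prior mean (`a'/b'`, `c'/d'`)
before the multiplier.

**Convergence.** The monitor is the mean Poisson log-pmf at posterior-mean
rates over the training non-zero entries (or a supplied validation entry
set). It is not the ELBO and not a true marginal likelihood — it is a cheap,
sparse-friendly surrogate whose stagnation tracks the fixed point well. The
`log(x!)` term is included (via log-gamma) so reported values are proper log
probabilities; it is constant in the parameters, so it cannot affect the
stopping decision. Training checkpoints every 10 sweeps and stops once the
absolute relative change is below 1e-5 (0.001%) at two consecutive
checkpoints, up to a cap of 1000 sweeps; a fit that hits the cap returns
with `converged=False` rather than raising.

**Restarts.** `fit` runs `n_trials` (default 10) independent initializations
whose RNG streams are spawned from one seed, so repeat runs are
bit-identical. With a validation entry set the trial with lowest validation
MAE wins (benchmark mode); otherwise the trial with the highest monitored
log-likelihood wins. Ties keep the earliest trial. Entry lists are
canonicalized to row-major order at construction, so fits are bit-identical
under any permutation of the input entries.

A note on the update equations: the cell block is the exact mirror of the
gene block — `γ` shapes and rates, then `κ_i^rte = b' + Σ_k γ_shp/γ_rte`
with the *cell* capacity prior rate `b'` as the constant. Any presentation
that repeats the gene-capacity update in the cell block is internally
inconsistent (it would leave `κ` never updated); the symmetric form is the
one consistent with the generative model and is what this package
implements.

## Benchmarking protocol

4% of non-zero entries are held out as a test set and 2% as validation
(round-half-even of `frac·T`), selected uniformly without replacement;
held-out entries are removed from the training matrix and therefore read as
zeros during training — the only representable choice in a non-zero store,
and it slightly deflates training totals. Predictions for held-out
coordinates are posterior-mean rates `E[θ_i]·E[β_g]`; errors can be computed
raw or after mapping both predictions and truths into a comparator's
normalized space. Normalizations: `log` is `log2(x+1)`; `rate` is counts per
median (cell scaled to sum 1, times the median cell total); `log_rate`
composes them. Inverses are the exact mathematical inverses (`2^y − 1`,
totals/median undone), so round-trips on integer counts are exact; negative
values map into `(−1, 0)` and are never clipped implicitly.

The comparator is a deliberately simple rank-K least-squares (truncated SVD)
reconstruction with per-gene Gaussian residual noise, standing in for the
Gaussian-generative-model family; it is used only for relative-performance
properties, not as a faithful reimplementation of any published method.

Posterior predictive checks sample `θ` and `β` from the variational Gammas
and counts from `Poisson(θβᵀ)`, ten replicates by default; per-cell and
per-gene coefficient-of-variation vectors (population sd / mean; zero-mean
rows yield NaN and are dropped) are averaged across replicates and compared
with the observed CVs by the two-sample Kolmogorov–Smirnov statistic
(scipy). Samplers working in a normalized space are inverse-transformed to
the count scale first; clipping impossible negative replicate values to zero
is an explicit option used for the Gaussian baseline.

The benchmark rule for choosing `K` is the smallest multiple of five
strictly greater than the cluster count (`7 → 10`, `10 → 15`).

## Gene selection

The prefilter keeps genes detected in at least 0.1% of cells, with the raw
cell count rounded *up* to the next multiple of 5 (a count already a
multiple of 5 stands), optionally intersected with a protein-coding
whitelist. Dropout scores: per-cell counts are normalized to sum to 1 (so
scores ignore sequencing depth); genes are ordered by descending mean
normalized expression, ties by gene index; `f_max` is the maximum detection
fraction in a 25-gene window centred on each gene, truncated (not padded) at
the ends of the ordering; `score = (f_max − f_g)/f_max ∈ [0, 1)`. Selection
takes scores strictly greater than 0.15, or at least six population standard
deviations above the mean (inclusive). When the standard deviation is
exactly zero the SD rule is suppressed — otherwise the inclusive comparison
would select every gene in the all-tied degenerate case. The direction of
the expression ordering and the choice of mean (vs total) normalized
expression are design choices; scores depend on the ordering only through
window membership, and the descending convention puts ties among
highly-expressed genes first.

## Synthetic data

`sample_generative` draws from the full hierarchy exactly as written above
and records every latent, so recovery and self-consistency tests have exact
ground truth. Default simulation hyperparameters are the fitting defaults
plus `b' = d' = 0.6`, chosen from the model's moments to give roughly 80–90%
zero entries and tens to hundreds of molecules per cell at a few hundred
genes — scaled-down UMI-like sparsity and over-dispersion. The simulator
reproduces what the model assumes: it does not emulate ambient RNA,
doublets, batch effects, cell-type structure beyond the factors, or
library-size confounding beyond what the capacity hierarchy implies, so
passing recovery tests demonstrate correctness of inference under the
model's own assumptions, not robustness to real-data artifacts.

`planted_factor_dataset` bypasses the Gamma hierarchy: disjoint gene blocks
with block-constant Poisson rates (`on_rate` for a cell group's own block,
`off_rate` elsewhere) make the ground-truth factors unambiguous.
`match_factors` L2-normalizes columns and finds the permutation maximizing
mean cosine similarity — exhaustively for `K ≤ 6`, by optimal assignment
otherwise.

## Problem sizes and numerical choices

Experiments in the test suite and acceptance script use a few hundred cells
and genes (e.g. 200 × 300 for convergence, 300 × 300 for recovery,
150 × 200 for prediction and PPC, 1e5 draws for the negative-binomial
check); these sizes give stable statistics while keeping the full suite fast
on a single core. `φ` is computed in log space with max-subtraction;
variational parameters remain strictly positive by construction (all updates
are sums of positive terms). A tiny instance reaches a floating-point fixed
point of the updates; large instances converge in likelihood long before the
parameters stop drifting along near-flat ridges, which is why convergence is
declared on the monitored likelihood rather than on parameter change.

## Known limitations

- The convergence monitor is a surrogate; it can stall early on very flat
  likelihood surfaces. More restarts (`n_trials`) are the remedy.
- Held-out entries train as zeros, slightly biasing totals downward at the
  default 6% holdout.
- The Gaussian comparator is intentionally minimal; benchmark ratios against
  it quantify the count model's advantage over a Gaussian low-rank fit, not
  over any specific published factorization.
- Batch minibatching, GPU execution, and automatic selection of `K` from
  held-out likelihood curves are out of scope.
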