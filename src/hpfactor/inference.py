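"""Coordinate-ascent variational inference over non-zero entries.

The Poisson observation x[i,g] = sum_k z[i,g,k] is augmented with per-factor
Poisson counts z[i,g,k] ~ Poisson(theta[i,k] * beta[g,k]); conditional on the
observed total, the z are multinomial with parameter phi[i,g] proportional to
the rates.  This makes every complete conditional conjugate, so all updates
are closed-form:

gene block (per gene g, factor k):
    lambda_shp[g,k] = c + sum_i x[i,g] phi[i,g,k]
    lambda_rte[g,k] = tau_shp[g]/tau_rte[g] + sum_i gamma_shp[i,k]/gamma_rte[i,k]
    tau_rte[g]      = d' + sum_k lambda_shp[g,k]/lambda_rte[g,k]

cell block (per cell i, factor k), symmetric:
    gamma_shp[i,k] = a + sum_g x[i,g] phi[i,g,k]
    gamma_rte[i,k] = kappa_shp[i]/kappa_rte[i] + sum_g lambda_shp[g,k]/lambda_rte[g,k]
    kappa_rte[i]   = b' + sum_k gamma_shp[i,k]/gamma_rte[i,k]

phi (per non-zero entry only):
    phi[i,g,k] ∝ exp{ psi(gamma_shp[i,k]) - log gamma_rte[i,k]
                      + psi(lambda_shp[g,k]) - log lambda_rte[g,k] }

Only the T non-zero entries ever enter the shape sums, and phi is held as a
T x K block, so a sweep costs O(NK + MK + TK) time and memory.  The very
first sweep uses a symmetric-Dirichlet phi rather than one derived from the
randomized initial state: recomputing phi before the first shape updates can
lock trials into redundant, symmetric factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .core import (
    FittedModel,
    HyperParams,
    SparseCountMatrix,
    VariationalState,
    estimate_inverse_budget_hyperparams,
    expected_rates,
    mean_poisson_log_likelihood,
)

__all__ = [
    "FitConfig",
    "init_state",
    "compute_phi",
    "update_gene_block",
    "update_cell_block",
    "run_iteration",
    "check_convergence",
    "fit",
]


@dataclass
class FitConfig:
    """Training loop settings.

    Convergence: every ``check_interval`` sweeps the monitored mean
    log-likelihood is checkpointed; training stops once the absolute relative
    change between consecutive checkpoints is below ``rel_tol`` (0.001% by
    default) ``required_consecutive`` times in a row.  ``monitor`` selects
    whether training non-zeros or a supplied validation entry set drives the
    checkpoints.
    """

    max_iter: int = 1000
    check_interval: int = 10
    rel_tol: float = 1e-5
    required_consecutive: int = 2
    n_trials: int = 10
    seed: int = 0
    monitor: str = "training"

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.check_interval < 1:
            raise ValueError("max_iter and check_interval must be positive")
        if not 0 < self.rel_tol < 1:
            raise ValueError("rel_tol must lie in (0, 1)")
        if self.required_consecutive < 1 or self.n_trials < 1:
            raise ValueError("required_consecutive and n_trials must be positive")
        if self.monitor not in ("training", "validation"):
            raise ValueError("monitor must be 'training' or 'validation'")


def init_state(
    X: SparseCountMatrix, hyper: HyperParams, seed: int | np.random.Generator
) -> tuple[VariationalState, np.ndarray]:
    """Randomized initial state plus the first-sweep Dirichlet phi block.

    Capacity shapes are set to their fixed values (kappa_shp = a' + K a,
    tau_shp = c' + K c) and never change afterwards.  Every other parameter
    starts at its prior value times an independent uniform multiplier in
    [0.5, 1.5]; for the loadings, whose prior rate is the (random) capacity,
    the capacity is taken at its prior mean (a'/b', c'/d') before the
    multiplier.  The returned phi block holds one symmetric-Dirichlet
    K-simplex per non-zero entry, used only in the first sweep.
    """
    hyper.require_complete()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N, M, K = X.n_cells, X.n_genes, hyper.K

    def mult(shape):
        return rng.uniform(0.5, 1.5, size=shape)

    kappa_shape = np.full(N, hyper.a_prime + K * hyper.a)
    tau_shape = np.full(M, hyper.c_prime + K * hyper.c)
    kappa_rate = hyper.b_prime * mult(N)
    tau_rate = hyper.d_prime * mult(M)
    gamma_shape = hyper.a * mult((N, K))
    # prior rate of theta is xi, taken at its prior mean a'/b'
    gamma_rate = (hyper.a_prime / hyper.b_prime) * mult((N, K))
    lambda_shape = hyper.c * mult((M, K))
    lambda_rate = (hyper.c_prime / hyper.d_prime) * mult((M, K))
    state = VariationalState(
        gamma_shape,
        gamma_rate,
        lambda_shape,
        lambda_rate,
        kappa_shape,
        kappa_rate,
        tau_shape,
        tau_rate,
    )
    phi_init = rng.dirichlet(np.ones(K), size=X.nnz) if X.nnz else np.empty((0, K))
    return state, phi_init


def compute_phi(
    state: VariationalState, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Multinomial factor-assignment parameters for the given entries.

    Returns a (T, K) row-stochastic array.  Computed in log space with
    max-subtraction so extreme Gamma expectations cannot overflow.
    """
    logw = (
        digamma(state.gamma_shape[rows])
        - np.log(state.gamma_rate[rows])
        + digamma(state.lambda_shape[cols])
        - np.log(state.lambda_rate[cols])
    )
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    return w


def _weighted_factor_sums(
    index: np.ndarray, weights: np.ndarray, phi: np.ndarray, size: int
) -> np.ndarray:
    """sum over entries of x * phi, grouped by cell or gene index."""
    K = phi.shape[1]
    out = np.empty((size, K))
    for k in range(K):
        out[:, k] = np.bincount(index, weights=weights * phi[:, k], minlength=size)
    return out


def update_gene_block(
    state: VariationalState,
    X: SparseCountMatrix,
    phi: np.ndarray,
    hyper: HyperParams,
) -> None:
    """In-place gene-side update: lambda shapes/rates then tau rates."""
    x = X.counts.astype(np.float64)
    state.lambda_shape = hyper.c + _weighted_factor_sums(X.cols, x, phi, X.n_genes)
    e_theta_sum = state.e_theta().sum(axis=0)  # length K, over all cells
    state.lambda_rate = state.e_eta()[:, None] + e_theta_sum[None, :]
    state.tau_rate = hyper.d_prime + state.e_beta().sum(axis=1)


def update_cell_block(
    state: VariationalState,
    X: SparseCountMatrix,
    phi: np.ndarray,
    hyper: HyperParams,
) -> None:
    """In-place cell-side update: gamma shapes/rates then kappa rates."""
    x = X.counts.astype(np.float64)
    state.gamma_shape = hyper.a + _weighted_factor_sums(X.rows, x, phi, X.n_cells)
    e_beta_sum = state.e_beta().sum(axis=0)  # length K, over all genes
    state.gamma_rate = state.e_xi()[:, None] + e_beta_sum[None, :]
    state.kappa_rate = hyper.b_prime + state.e_theta().sum(axis=1)


def run_iteration(
    state: VariationalState,
    X: SparseCountMatrix,
    phi: np.ndarray,
    hyper: HyperParams,
) -> np.ndarray:
    """One full CAVI sweep in the fixed order: gene block, cell block, phi.

    ``phi`` is the multinomial block to use for this sweep's shape updates
    (the Dirichlet initialization on the first sweep).  Returns the phi block
    for the next sweep, recomputed from the updated state.
    """
    update_gene_block(state, X, phi, hyper)
    update_cell_block(state, X, phi, hyper)
    return compute_phi(state, X.rows, X.cols)


def check_convergence(history: list[float], config: FitConfig) -> bool:
    """True iff the last ``required_consecutive`` checkpoint-to-checkpoint
    absolute relative changes are each below ``rel_tol``."""
    need = config.required_consecutive
    if len(history) < need + 1:
        return False
    for new, old in zip(history[-need:], history[-need - 1 : -1]):
        denom = abs(old)
        rel = abs(new - old) / denom if denom > 0 else abs(new - old)
        if not rel < config.rel_tol:
            return False
    return True


def _single_trial(
    X: SparseCountMatrix,
    hyper: HyperParams,
    config: FitConfig,
    rng: np.random.Generator,
    monitor_entries: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> tuple[VariationalState, list[tuple[int, float]], bool]:
    state, phi = init_state(X, hyper, rng)
    mrows, mcols, mcounts = monitor_entries
    history: list[tuple[int, float]] = []
    values: list[float] = []
    converged = False
    for it in range(1, config.max_iter + 1):
        phi = run_iteration(state, X, phi, hyper)
        if it % config.check_interval == 0 or it == config.max_iter:
            ll = mean_poisson_log_likelihood(state, mrows, mcols, mcounts)
            if not np.isfinite(ll):
                raise FloatingPointError(f"non-finite monitored value at sweep {it}")
            history.append((it, ll))
            values.append(ll)
            if check_convergence(values, config):
                converged = True
                break
    return state, history, converged


def fit(
    X: SparseCountMatrix,
    hyper: HyperParams,
    config: FitConfig,
    validation: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> FittedModel:
    """Run ``config.n_trials`` independent restarts and keep the best.

    If a validation entry set (rows, cols, counts) is supplied, the trial
    with the lowest validation mean absolute error wins (benchmark mode);
    otherwise the trial with the highest monitored mean log-likelihood wins.
    All randomness descends from ``config.seed`` through spawned child
    streams, so repeat runs are bit-identical.
    """
    if X.nnz == 0:
        raise ValueError("cannot fit an all-zero matrix")
    if not hyper.complete:
        b_prime, d_prime = estimate_inverse_budget_hyperparams(
            X, hyper.a_prime, hyper.c_prime
        )
        hyper = HyperParams(
            K=hyper.K,
            a=hyper.a,
            a_prime=hyper.a_prime,
            b_prime=b_prime,
            c=hyper.c,
            c_prime=hyper.c_prime,
            d_prime=d_prime,
        )
    if config.monitor == "validation":
        if validation is None:
            raise ValueError("monitor='validation' requires a validation entry set")
        monitor_entries = validation
    else:
        monitor_entries = (X.rows, X.cols, X.counts)

    children = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    best = None
    errors: list[str] = []
    for t, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            state, history, converged = _single_trial(
                X, hyper, config, rng, monitor_entries
            )
        except FloatingPointError as exc:  # pragma: no cover - defensive
            errors.append(f"trial {t}: {exc}")
            continue
        if validation is not None:
            vrows, vcols, vcounts = validation
            pred = expected_rates(state, vrows, vcols)
            crit = -float(np.mean(np.abs(pred - vcounts)))  # higher is better
        else:
            crit = history[-1][1]
        if best is None or crit > best[0]:
            best = (crit, state, history, converged)
    if best is None:
        raise RuntimeError("no trial completed: " + "; ".join(errors))
    _, state, history, converged = best
    return FittedModel(
        hyper=hyper,
        state=state,
        loss_history=history,
        converged=converged,
        seed=config.seed,
        n_trials=config.n_trials,
        gene_names=list(X.gene_names),
        cell_ids=list(X.cell_ids),
    )
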