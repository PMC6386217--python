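"""Synthetic count data: the model's own generative process and planted factors.

``sample_generative`` draws a dataset from the full Gamma-Poisson hierarchy
with recorded ground truth, producing sparse, over-dispersed UMI-like counts
(each gene's marginal is a negative binomial, since a Gamma-mixed Poisson is
negative binomial).  ``planted_factor_dataset`` instead builds unambiguous
block structure — disjoint gene blocks with elevated Poisson rates per cell
group — for parameter-recovery experiments, and ``match_factors`` scores a
fitted factorization against the planted truth up to column permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import HyperParams, SparseCountMatrix

__all__ = [
    "SyntheticTruth",
    "default_sim_hyper",
    "sample_generative",
    "planted_factor_dataset",
    "match_factors",
]


@dataclass
class SyntheticTruth:
    """Ground truth latents and the counts sampled from them."""

    xi: np.ndarray
    eta: np.ndarray
    theta: np.ndarray
    beta: np.ndarray
    counts: SparseCountMatrix
    hyper: HyperParams
    seed: int


def default_sim_hyper(K: int = 3) -> HyperParams:
    """Simulation hyperparameters giving scaled-down UMI-like data.

    a = c = 0.3 and a' = c' = 1 match the fitting defaults; the inverse-budget
    rates b' = d' = 0.6 put typical entry rates well below one molecule, i.e.
    roughly 80-90% zero entries and tens to hundreds of molecules per cell at
    a few hundred genes — sparse and over-dispersed like real UMI matrices,
    at desk scale.
    """
    return HyperParams(K=K, a=0.3, a_prime=1.0, b_prime=0.6, c=0.3, c_prime=1.0, d_prime=0.6)


def sample_generative(
    N: int, M: int, hyper: HyperParams, seed: int = 0
) -> SyntheticTruth:
    """Draw a dataset from the hierarchical Gamma-Poisson process.

    xi_i ~ Gamma(a', b'); theta_{i,k} ~ Gamma(a, xi_i); eta_g ~ Gamma(c', d');
    beta_{g,k} ~ Gamma(c, eta_g); x_{i,g} ~ Poisson(theta_i . beta_g).
    Capacities are Gamma *rates* of the loadings, so a larger capacity draw
    means a lower-output cell or gene.  Zeros are dropped from storage.
    Deterministic given (N, M, hyper, seed).
    """
    if N < 1 or M < 1:
        raise ValueError("N and M must be >= 1")
    hyper.require_complete()
    rng = np.random.default_rng(seed)
    K = hyper.K
    xi = rng.gamma(hyper.a_prime, 1.0 / hyper.b_prime, size=N)
    theta = rng.gamma(hyper.a, 1.0 / xi[:, None], size=(N, K))
    eta = rng.gamma(hyper.c_prime, 1.0 / hyper.d_prime, size=M)
    beta = rng.gamma(hyper.c, 1.0 / eta[:, None], size=(M, K))
    counts = rng.poisson(theta @ beta.T)
    return SyntheticTruth(
        xi=xi,
        eta=eta,
        theta=theta,
        beta=beta,
        counts=SparseCountMatrix.from_dense(counts),
        hyper=hyper,
        seed=seed,
    )


def planted_factor_dataset(
    n_cells_per_group: int,
    M: int,
    K_true: int,
    on_rate: float = 2.0,
    off_rate: float = 0.05,
    seed: int = 0,
) -> tuple[SparseCountMatrix, np.ndarray, np.ndarray]:
    """Block-structured counts with one dominant factor per cell group.

    Genes are partitioned into K_true disjoint blocks; cells in group k draw
    Poisson counts at ``on_rate`` on block k's genes and ``off_rate``
    elsewhere.  Returns (counts, group labels, true beta) where true beta is
    the M x K_true block-indicator rate matrix.
    """
    if K_true < 2:
        raise ValueError("K_true must be >= 2")
    if M < K_true:
        raise ValueError("need at least one gene per factor")
    if not on_rate >= off_rate > 0:
        raise ValueError("need on_rate >= off_rate > 0")
    rng = np.random.default_rng(seed)
    N = n_cells_per_group * K_true
    labels = np.repeat(np.arange(K_true), n_cells_per_group)
    block = np.array_split(np.arange(M), K_true)
    beta_true = np.full((M, K_true), off_rate)
    for k, genes in enumerate(block):
        beta_true[genes, k] = on_rate
    rates = np.full((N, M), off_rate)
    for k, genes in enumerate(block):
        rates[np.ix_(labels == k, genes)] = on_rate
    counts = rng.poisson(rates)
    X = SparseCountMatrix.from_dense(counts)
    return X, labels, beta_true


def match_factors(
    true_beta: np.ndarray, estimated: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best factor-to-factor matching between truth and estimate.

    Columns of both matrices are L2-normalized; the permutation maximizing
    the mean cosine similarity is found exactly (exhaustive for K <= 6,
    optimal assignment otherwise).  Returns (perm, per-factor similarity)
    where estimated column perm[k] matches true column k.
    """
    true_beta = np.asarray(true_beta, dtype=np.float64)
    estimated = np.asarray(estimated, dtype=np.float64)
    if true_beta.shape != estimated.shape:
        raise ValueError("true and estimated factor matrices must have equal shapes")
    K = true_beta.shape[1]

    def unit(A):
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        return A / norms

    sim = unit(true_beta).T @ unit(estimated)  # K x K cosine matrix
    if K <= 6:
        best_perm, best_val = None, -np.inf
        for perm in permutations(range(K)):
            val = sim[np.arange(K), perm].sum()
            if val > best_val:
                best_perm, best_val = perm, val
        perm = np.array(best_perm)
    else:
        _, perm = linear_sum_assignment(-sim)
    return perm, sim[np.arange(K), perm]
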