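"""Core data types, hyperparameter estimation, rates, likelihood, and scores.

The model factorizes a cells x genes matrix of molecular (UMI) counts
``x[i, g] ~ Poisson(theta[i] . beta[g])`` where the non-negative loadings
``theta`` (cells x K) and ``beta`` (genes x K) have Gamma priors whose rate
parameters are themselves Gamma-distributed per-cell and per-gene "inverse
budgets" (capacities) ``xi`` and ``eta``:

    xi_i  ~ Gamma(a', b')      theta_{i,k} ~ Gamma(a, xi_i)
    eta_g ~ Gamma(c', d')      beta_{g,k}  ~ Gamma(c, eta_g)

A larger capacity value means a smaller expected loading, hence lower
transcriptional output for that cell or gene.  Inference (see
:mod:`hpfactor.inference`) produces independent Gamma variational posteriors
for every latent variable; this module defines the containers for those
posteriors and everything computed from their means: expected Poisson rates,
the Poisson log-likelihood used as a convergence monitor, and the cell/gene
scores used for gene-signature ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.special import gammaln

__all__ = [
    "SparseCountMatrix",
    "HyperParams",
    "VariationalState",
    "FittedModel",
    "estimate_inverse_budget_hyperparams",
    "expected_rates",
    "mean_poisson_log_likelihood",
    "cell_scores",
    "gene_scores",
    "rank_genes",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally unusable (e.g. zero variance)."""


@dataclass
class SparseCountMatrix:
    """Coordinate-format cells x genes UMI count matrix.

    Zeros are implicit: only strictly positive counts are stored.  Duplicate
    (cell, gene) coordinates are rejected at construction.
    """

    n_cells: int
    n_genes: int
    rows: np.ndarray  # cell index per non-zero entry
    cols: np.ndarray  # gene index per non-zero entry
    counts: np.ndarray  # positive integer count per entry
    cell_ids: list[str] = field(default_factory=list)
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.rows.shape != self.cols.shape or self.rows.shape != self.counts.shape:
            raise ValueError("rows, cols and counts must have equal length")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("matrix must have at least one cell and one gene")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                rounded = np.rint(self.counts)
                if not np.allclose(self.counts, rounded, rtol=0, atol=0):
                    raise ValueError("counts must be integers")
                self.counts = rounded.astype(np.int64)
            else:
                self.counts = self.counts.astype(np.int64)
            if (self.counts < 1).any():
                raise ValueError("stored counts must be >= 1 (zeros are implicit)")
            if (
                self.rows.min() < 0
                or self.rows.max() >= self.n_cells
                or self.cols.min() < 0
                or self.cols.max() >= self.n_genes
            ):
                raise ValueError("entry coordinates out of range")
            # canonical row-major entry order: fits are then bit-identical
            # under any permutation of the input entry list
            flat = self.rows * self.n_genes + self.cols
            order = np.argsort(flat, kind="stable")
            flat = flat[order]
            if np.any(flat[1:] == flat[:-1]):
                raise ValueError("duplicate (cell, gene) coordinates")
            self.rows = self.rows[order]
            self.cols = self.cols[order]
            self.counts = self.counts[order]
        else:
            self.counts = self.counts.astype(np.int64)
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.n_cells)]
        if not self.gene_names:
            self.gene_names = [f"gene{g}" for g in range(self.n_genes)]
        if len(self.cell_ids) != self.n_cells or len(self.gene_names) != self.n_genes:
            raise ValueError("label lengths must match matrix dimensions")

    @property
    def nnz(self) -> int:
        return int(self.counts.size)

    @classmethod
    def from_dense(
        cls,
        dense: np.ndarray,
        cell_ids: Sequence[str] | None = None,
        gene_names: Sequence[str] | None = None,
    ) -> "SparseCountMatrix":
        dense = np.asarray(dense)
        rows, cols = np.nonzero(dense)
        return cls(
            n_cells=dense.shape[0],
            n_genes=dense.shape[1],
            rows=rows,
            cols=cols,
            counts=dense[rows, cols],
            cell_ids=list(cell_ids) if cell_ids is not None else [],
            gene_names=list(gene_names) if gene_names is not None else [],
        )

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n_cells, self.n_genes), dtype=np.int64)
        out[self.rows, self.cols] = self.counts
        return out

    def to_coo(self) -> coo_matrix:
        return coo_matrix(
            (self.counts, (self.rows, self.cols)), shape=(self.n_cells, self.n_genes)
        )

    def cell_totals(self) -> np.ndarray:
        """Total molecules per cell, including implicit zeros."""
        return np.bincount(self.rows, weights=self.counts, minlength=self.n_cells)

    def gene_totals(self) -> np.ndarray:
        """Total molecules per gene, including implicit zeros."""
        return np.bincount(self.cols, weights=self.counts, minlength=self.n_genes)

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells in which each gene is detected."""
        return np.bincount(self.cols, minlength=self.n_genes)


@dataclass
class HyperParams:
    """Gamma hyperparameters of the hierarchical model plus the factor count K.

    ``a``/``c`` are the loading shapes (0.3 by default, favouring sparsity);
    ``a_prime``/``b_prime`` and ``c_prime``/``d_prime`` are shape/rate of the
    cell and gene capacity priors.  ``b_prime`` and ``d_prime`` are usually
    set empirically from the data (see
    :func:`estimate_inverse_budget_hyperparams`).  Note that here the capacity
    hyperpriors are parameterized by their rates directly (Gamma(a', b')), not
    by a mean a'/b' as in some presentations of Poisson factorization — users
    converting hyperparameters from the mean convention must invert the ratio.
    """

    K: int
    a: float = 0.3
    a_prime: float = 1.0
    b_prime: float | None = None
    c: float = 0.3
    c_prime: float = 1.0
    d_prime: float | None = None

    def __post_init__(self) -> None:
        if int(self.K) != self.K or self.K < 1:
            raise ValueError("K must be a positive integer")
        self.K = int(self.K)
        for name in ("a", "a_prime", "c", "c_prime"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("b_prime", "d_prime"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def complete(self) -> bool:
        return self.b_prime is not None and self.d_prime is not None

    def require_complete(self) -> None:
        if not self.complete:
            raise ValueError("b_prime and d_prime must be set (estimate from data)")


@dataclass
class VariationalState:
    """Mean-field Gamma variational parameters.

    gamma_* (cells x K) parameterize q(theta), lambda_* (genes x K)
    parameterize q(beta), kappa_* (cells) parameterize q(xi) and tau_* (genes)
    parameterize q(eta).  The per-entry multinomial phi over factor
    assignments is never stored here; it is recomputed from the state on
    demand.  kappa_shape and tau_shape are constants fixed at initialization
    (a' + K a and c' + K c respectively).
    """

    gamma_shape: np.ndarray
    gamma_rate: np.ndarray
    lambda_shape: np.ndarray
    lambda_rate: np.ndarray
    kappa_shape: np.ndarray
    kappa_rate: np.ndarray
    tau_shape: np.ndarray
    tau_rate: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "gamma_shape",
            "gamma_rate",
            "lambda_shape",
            "lambda_rate",
            "kappa_shape",
            "kappa_rate",
            "tau_shape",
            "tau_rate",
        ):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
        if self.gamma_shape.shape != self.gamma_rate.shape:
            raise ValueError("gamma shape/rate dimension mismatch")
        if self.lambda_shape.shape != self.lambda_rate.shape:
            raise ValueError("lambda shape/rate dimension mismatch")

    @property
    def n_cells(self) -> int:
        return self.gamma_shape.shape[0]

    @property
    def n_genes(self) -> int:
        return self.lambda_shape.shape[0]

    @property
    def K(self) -> int:
        return self.gamma_shape.shape[1]

    def validate(self) -> None:
        for name in (
            "gamma_shape",
            "gamma_rate",
            "lambda_shape",
            "lambda_rate",
            "kappa_shape",
            "kappa_rate",
            "tau_shape",
            "tau_rate",
        ):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
                raise ValueError(f"{name} must be strictly positive and finite")

    def e_theta(self) -> np.ndarray:
        return self.gamma_shape / self.gamma_rate

    def e_beta(self) -> np.ndarray:
        return self.lambda_shape / self.lambda_rate

    def e_xi(self) -> np.ndarray:
        return self.kappa_shape / self.kappa_rate

    def e_eta(self) -> np.ndarray:
        return self.tau_shape / self.tau_rate

    def copy(self) -> "VariationalState":
        return VariationalState(
            *(
                getattr(self, name).copy()
                for name in (
                    "gamma_shape",
                    "gamma_rate",
                    "lambda_shape",
                    "lambda_rate",
                    "kappa_shape",
                    "kappa_rate",
                    "tau_shape",
                    "tau_rate",
                )
            )
        )


@dataclass
class FittedModel:
    """A converged (or max-iteration) variational fit with provenance."""

    hyper: HyperParams
    state: VariationalState
    loss_history: list[tuple[int, float]]
    converged: bool
    seed: int
    n_trials: int
    gene_names: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)


def estimate_inverse_budget_hyperparams(
    X: SparseCountMatrix, a_prime: float = 1.0, c_prime: float = 1.0
) -> tuple[float, float]:
    """Set the capacity rate hyperparameters from the data.

    The rates are chosen to preserve the empirical variance-to-mean ratio of
    total molecules per cell (for ``b'``) and per gene (for ``d'``)::

        b' = a' * E[molecules per cell] / Var[molecules per cell]
        d' = c' * E[molecules per gene] / Var[molecules per gene]

    Totals include implicit zeros; variances use the population (denominator
    n) estimator.
    """
    if X.n_cells < 2 or X.n_genes < 2:
        raise DegenerateInputError("need at least 2 cells and 2 genes")
    if a_prime <= 0 or c_prime <= 0:
        raise ValueError("a_prime and c_prime must be strictly positive")
    cell_tot = X.cell_totals()
    gene_tot = X.gene_totals()
    cell_var = float(np.var(cell_tot))
    gene_var = float(np.var(gene_tot))
    if cell_var == 0:
        raise DegenerateInputError("per-cell molecule totals have zero variance")
    if gene_var == 0:
        raise DegenerateInputError("per-gene molecule totals have zero variance")
    b_prime = a_prime * float(np.mean(cell_tot)) / cell_var
    d_prime = c_prime * float(np.mean(gene_tot)) / gene_var
    return b_prime, d_prime


def expected_rates(
    state: VariationalState, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Posterior-mean Poisson rate E[theta_i] . E[beta_g] at given coordinates."""
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    if rows.size and (
        rows.min() < 0
        or rows.max() >= state.n_cells
        or cols.min() < 0
        or cols.max() >= state.n_genes
    ):
        raise IndexError("coordinates out of range")
    return np.einsum("ik,ik->i", state.e_theta()[rows], state.e_beta()[cols])


def mean_poisson_log_likelihood(
    state: VariationalState,
    rows: np.ndarray,
    cols: np.ndarray,
    counts: np.ndarray,
) -> float:
    """Mean Poisson log pmf at posterior-mean rates over the given entries.

    This is the quantity monitored for convergence: cheap to evaluate on the
    sparse entry set, and includes the log(x!) term so the values are proper
    log probabilities.  Zero counts are allowed (held-out entries).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size == 0:
        raise ValueError("entry list must be non-empty")
    lam = expected_rates(state, rows, cols)
    ll = counts * np.log(lam) - lam - gammaln(counts + 1.0)
    return float(np.mean(ll))


def cell_scores(model: FittedModel) -> np.ndarray:
    """Cell-by-factor score matrix: E[xi_i | x] * E[theta_{i,k} | x].

    Multiplying the loading by the posterior-mean inverse budget adjusts each
    cell's factor association for its learned transcriptional output.
    """
    st = model.state
    return st.e_xi()[:, None] * st.e_theta()


def gene_scores(model: FittedModel) -> np.ndarray:
    """Gene-by-factor score matrix: E[eta_g | x] * E[beta_{g,k} | x]."""
    st = model.state
    return st.e_eta()[:, None] * st.e_beta()


def rank_genes(model: FittedModel, factor: int, top_n: int) -> list[str]:
    """Top ``top_n`` gene names for one factor, by descending gene score.

    Ties break by ascending gene index, so the ordering is deterministic.
    """
    st = model.state
    if not 0 <= factor < st.K:
        raise IndexError(f"factor {factor} out of range for K={st.K}")
    if not 1 <= top_n <= st.n_genes:
        raise ValueError(f"top_n must be in [1, {st.n_genes}]")
    scores = gene_scores(model)[:, factor]
    order = np.argsort(-scores, kind="stable")
    names = model.gene_names or [f"gene{g}" for g in range(st.n_genes)]
    return [names[g] for g in order[:top_n]]
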