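"""Held-out benchmarking and posterior predictive checks.

Benchmarking holds out a small fraction of the *non-zero* entries (4% test,
2% validation by default) so the training matrix keeps its native sparsity
structure, trains on the remainder, and scores predictions of the held-out
counts.  Posterior predictive checks sample replicate count matrices from the
fitted variational posterior and compare the per-cell and per-gene
coefficient-of-variation distributions against the observed data via the
two-sample Kolmogorov-Smirnov statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import FittedModel, SparseCountMatrix, expected_rates

__all__ = [
    "EntrySplit",
    "NormMeta",
    "split_nonzeros",
    "normalize_counts",
    "normalize_values",
    "inverse_transform",
    "predict_heldout",
    "prediction_error",
    "posterior_predictive_sample",
    "cv_vector",
    "ppc_cv_ks",
    "ks_statistic",
    "gaussian_baseline",
    "select_k_benchmark",
]

_METHODS = ("log", "rate", "log_rate")


@dataclass
class EntrySplit:
    """Partition of a matrix's non-zero entries into train/validation/test.

    ``train`` is a count matrix with the held-out entries removed (implicitly
    zero); ``validation`` and ``test`` are (rows, cols, counts) triples.
    """

    train: SparseCountMatrix
    validation: tuple[np.ndarray, np.ndarray, np.ndarray]
    test: tuple[np.ndarray, np.ndarray, np.ndarray]
    seed: int


@dataclass
class NormMeta:
    """Per-cell totals and their median, kept so transforms are invertible."""

    cell_totals: np.ndarray
    median_total: float


def split_nonzeros(
    X: SparseCountMatrix,
    test_frac: float = 0.04,
    val_frac: float = 0.02,
    seed: int = 0,
) -> EntrySplit:
    """Uniformly partition non-zero entries into train/validation/test.

    Holdout sizes are round-half-even of frac * T.  Deterministic given
    ``seed``.
    """
    for frac in (test_frac, val_frac):
        if not 0 <= frac < 1:
            raise ValueError("fractions must lie in [0, 1)")
    if test_frac + val_frac >= 1:
        raise ValueError("test_frac + val_frac must be < 1")
    T = X.nnz
    n_test = int(np.rint(test_frac * T))
    n_val = int(np.rint(val_frac * T))
    perm = np.random.default_rng(seed).permutation(T)
    test_idx = np.sort(perm[:n_test])
    val_idx = np.sort(perm[n_test : n_test + n_val])
    train_idx = np.sort(perm[n_test + n_val :])
    train = SparseCountMatrix(
        n_cells=X.n_cells,
        n_genes=X.n_genes,
        rows=X.rows[train_idx],
        cols=X.cols[train_idx],
        counts=X.counts[train_idx],
        cell_ids=list(X.cell_ids),
        gene_names=list(X.gene_names),
    )
    pick = lambda idx: (X.rows[idx], X.cols[idx], X.counts[idx])
    return EntrySplit(train=train, validation=pick(val_idx), test=pick(test_idx), seed=seed)


def _check_method(method: str) -> None:
    if method not in _METHODS:
        raise ValueError(f"unknown normalization {method!r}; expected one of {_METHODS}")


def normalize_counts(
    X: SparseCountMatrix | np.ndarray,
    method: str,
    meta: NormMeta | None = None,
) -> tuple[np.ndarray, NormMeta]:
    """Normalize a count matrix for benchmarking.

    log:      y = log2(x + 1)
    rate:     counts per median — each cell scaled to sum 1, times the median
              molecules per cell
    log_rate: log transform applied to the rate-normalized values
    """
    _check_method(method)
    dense = X.to_dense() if isinstance(X, SparseCountMatrix) else np.asarray(X)
    dense = dense.astype(np.float64)
    if meta is None:
        cell_totals = dense.sum(axis=1)
        meta = NormMeta(cell_totals=cell_totals, median_total=float(np.median(cell_totals)))
    if method == "log":
        return np.log2(dense + 1.0), meta
    if np.any(meta.cell_totals <= 0):
        raise ValueError("rate normalization requires every cell total > 0")
    rate = dense / meta.cell_totals[:, None] * meta.median_total
    if method == "rate":
        return rate, meta
    return np.log2(rate + 1.0), meta


def normalize_values(
    values: np.ndarray, cell_index: np.ndarray, method: str, meta: NormMeta
) -> np.ndarray:
    """Apply a normalization to per-entry values given their cell indices."""
    _check_method(method)
    values = np.asarray(values, dtype=np.float64)
    if method == "log":
        return np.log2(values + 1.0)
    rate = values / meta.cell_totals[cell_index] * meta.median_total
    if method == "rate":
        return rate
    return np.log2(rate + 1.0)


def inverse_transform(Y: np.ndarray, method: str, meta: NormMeta) -> np.ndarray:
    """Exact mathematical inverse of :func:`normalize_counts`.

    Round-trips integer counts exactly.  Negative inputs under log methods
    map into (-1, 0) and are passed through unchanged; clipping to zero is an
    explicit downstream option, never implicit here.
    """
    _check_method(method)
    Y = np.asarray(Y, dtype=np.float64)
    if method == "log":
        return np.exp2(Y) - 1.0
    if method == "log_rate":
        Y = np.exp2(Y) - 1.0
    return Y * meta.cell_totals[:, None] / meta.median_total


def predict_heldout(
    model: FittedModel,
    rows: np.ndarray,
    cols: np.ndarray,
) -> np.ndarray:
    """Expected-rate predictions, on the count scale, for held-out coordinates."""
    return expected_rates(model.state, rows, cols)


def prediction_error(predicted: np.ndarray, observed: np.ndarray, metric: str = "mse") -> float:
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal shapes")
    if predicted.size == 0:
        raise ValueError("empty vectors")
    diff = predicted - observed
    if metric == "mse":
        return float(np.mean(diff**2))
    if metric == "mae":
        return float(np.mean(np.abs(diff)))
    raise ValueError(f"unknown metric {metric!r}")


def posterior_predictive_sample(
    model: FittedModel, seed: int | np.random.Generator
) -> np.ndarray:
    """One replicate N x M count matrix from the fitted variational posterior.

    theta and beta are drawn from their variational Gammas and their inner
    product drives a Poisson draw per matrix entry.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    st = model.state
    theta = rng.gamma(st.gamma_shape, 1.0 / st.gamma_rate)
    beta = rng.gamma(st.lambda_shape, 1.0 / st.lambda_rate)
    return rng.poisson(theta @ beta.T)


def cv_vector(matrix: np.ndarray, axis: str) -> np.ndarray:
    """Coefficient of variation (population sd / mean) per cell or per gene.

    ``per_cell`` takes the CV across genes within each cell; ``per_gene``
    across cells for each gene.  Rows/columns with zero mean yield NaN and
    are excluded from downstream KS comparisons.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    ax = {"per_cell": 1, "per_gene": 0}.get(axis)
    if ax is None:
        raise ValueError("axis must be 'per_cell' or 'per_gene'")
    mean = matrix.mean(axis=ax)
    sd = matrix.std(axis=ax)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return cv


def ks_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup |ECDF_a - ECDF_b|)."""
    sample_a = np.asarray(sample_a, dtype=np.float64)
    sample_b = np.asarray(sample_b, dtype=np.float64)
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("samples must be non-empty")
    return float(stats.ks_2samp(sample_a, sample_b, method="asymp").statistic)


def ppc_cv_ks(
    model: FittedModel,
    X_obs: SparseCountMatrix | np.ndarray,
    n_reps: int = 10,
    seed: int = 0,
    sampler=None,
    clip_negative: bool = False,
) -> tuple[float, float, dict[str, np.ndarray]]:
    """Posterior predictive check on coefficient-of-variation distributions.

    Draws ``n_reps`` replicate matrices (by default from
    :func:`posterior_predictive_sample`), averages each cell's and gene's CV
    across replicates, and returns the two-sample KS statistics between
    observed and simulated CV distributions (per-cell, per-gene) plus the
    averaged CV vectors.  ``clip_negative`` zeroes impossible negative
    replicate values before computing CVs (relevant for Gaussian samplers on
    the count scale).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dense_obs = X_obs.to_dense() if isinstance(X_obs, SparseCountMatrix) else np.asarray(X_obs)
    rng = np.random.default_rng(seed)
    cell_cvs, gene_cvs = [], []
    for _ in range(n_reps):
        rep = (
            posterior_predictive_sample(model, rng)
            if sampler is None
            else sampler(rng)
        ).astype(np.float64)
        if clip_negative:
            rep = np.clip(rep, 0.0, None)
        cell_cvs.append(cv_vector(rep, "per_cell"))
        gene_cvs.append(cv_vector(rep, "per_gene"))
    import warnings as _warnings

    with _warnings.catch_warnings():
        # a cell/gene undefined (zero-mean) in every replicate yields NaN,
        # dropped below before the KS comparison
        _warnings.simplefilter("ignore", RuntimeWarning)
        sim_cell = np.nanmean(np.vstack(cell_cvs), axis=0)
        sim_gene = np.nanmean(np.vstack(gene_cvs), axis=0)
    obs_cell = cv_vector(dense_obs, "per_cell")
    obs_gene = cv_vector(dense_obs, "per_gene")
    drop = lambda v: v[np.isfinite(v)]
    ks_cell = ks_statistic(drop(obs_cell), drop(sim_cell))
    ks_gene = ks_statistic(drop(obs_gene), drop(sim_gene))
    return ks_cell, ks_gene, {
        "sim_cell_cv": sim_cell,
        "sim_gene_cv": sim_gene,
        "obs_cell_cv": obs_cell,
        "obs_gene_cv": obs_gene,
    }


@dataclass
class GaussianBaseline:
    """Rank-K least-squares comparator with per-gene Gaussian residual noise.

    A deliberately simple stand-in for Gaussian-model factorizations: the
    reconstruction is the truncated SVD of the (normalized) matrix, and
    replicates add independent Gaussian noise with per-gene residual
    variance.
    """

    reconstruction: np.ndarray
    residual_sd: np.ndarray  # per gene

    def sample(self, rng: np.random.Generator, clip_negative: bool = False) -> np.ndarray:
        rep = self.reconstruction + rng.normal(size=self.reconstruction.shape) * self.residual_sd
        if clip_negative:
            rep = np.clip(rep, 0.0, None)
        return rep


def gaussian_baseline(X_norm: np.ndarray, K: int, seed: int = 0) -> GaussianBaseline:
    """Fit the rank-K Gaussian comparator to a real-valued matrix."""
    X_norm = np.asarray(X_norm, dtype=np.float64)
    N, M = X_norm.shape
    if not 1 <= K <= min(N, M):
        raise ValueError(f"K must be in [1, {min(N, M)}]")
    U, s, Vt = np.linalg.svd(X_norm, full_matrices=False)
    recon = (U[:, :K] * s[:K]) @ Vt[:K]
    resid = X_norm - recon
    residual_sd = resid.std(axis=0)
    return GaussianBaseline(reconstruction=recon, residual_sd=residual_sd)


def select_k_benchmark(n_clusters: int) -> int:
    """Benchmark rule for the factor count: smallest multiple of five
    strictly greater than the number of clusters."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    return 5 * (n_clusters // 5) + 5
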