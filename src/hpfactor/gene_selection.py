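"""Gene prefiltering and dropout-score variable-gene selection.

The prefilter keeps genes detected in at least 0.1% of cells (the raw count
rounded up to the next multiple of 5), optionally intersected with a
protein-coding whitelist.  The dropout score flags genes detected in fewer
cells than expression-matched neighbours — likely markers of cellular
subpopulations: with genes ordered by mean cell-normalized expression, each
gene's detection fraction f_g is compared with the maximum fraction f_max in
a rolling window centred on it, and score = (f_max - f_g) / f_max.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SparseCountMatrix

__all__ = ["prefilter_genes", "rolling_max", "dropout_scores", "select_variable_genes"]


def rolling_max(values: np.ndarray, window: int) -> np.ndarray:
    """Maximum over a centred window of ``window`` positions around each entry.

    Windows are truncated at the ends of the vector (never padded), so every
    output is the max of at least one value, and the value itself is always
    inside its own window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    return (
        pd.Series(np.asarray(values, dtype=np.float64))
        .rolling(window, center=True, min_periods=1)
        .max()
        .to_numpy()
    )


def prefilter_genes(
    X: SparseCountMatrix,
    min_frac: float = 0.001,
    whitelist: set[str] | None = None,
) -> np.ndarray:
    """Boolean mask over genes passing the prevalence filter.

    The minimum number of expressing cells is ceil(min_frac * N) rounded up
    to the next multiple of 5 (values already a multiple of 5 are kept).
    Genes outside ``whitelist`` (when given) are masked regardless of
    prevalence.
    """
    raw = int(np.ceil(min_frac * X.n_cells))
    threshold = raw if raw % 5 == 0 else 5 * (raw // 5 + 1)
    mask = X.cells_per_gene() >= threshold
    if whitelist is not None:
        mask &= np.array([name in whitelist for name in X.gene_names])
    if not mask.any():
        raise ValueError("no genes pass the prevalence filter")
    return mask


def dropout_scores(X: SparseCountMatrix, window: int = 25) -> pd.DataFrame:
    """Dropout score per gene.

    Per-cell counts are normalized to sum to 1 (so scores are invariant to
    cell sequencing depth); genes are ordered by descending mean normalized
    expression (ties by ascending gene index); f_max is the rolling-window
    maximum of the detection fraction f_g, with windows truncated at the ends
    of the ordering.  Returns a DataFrame indexed by gene with columns
    ``gene_index``, ``f``, ``f_max``, ``score``, in original gene order.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    totals = X.cell_totals()
    if np.any(totals[np.unique(X.rows)] <= 0):  # pragma: no cover - unreachable
        raise ValueError("cell totals must be positive")
    norm = X.counts / totals[X.rows]
    mean_expr = np.bincount(X.cols, weights=norm, minlength=X.n_genes) / X.n_cells
    f = X.cells_per_gene() / X.n_cells
    if np.any(f == 0):
        raise ValueError("every gene must be detected in at least one cell; prefilter first")
    # descending expression, stable in gene index
    order = np.lexsort((np.arange(X.n_genes), -mean_expr))
    f_max_ordered = rolling_max(f[order], window)
    f_max = np.empty(X.n_genes)
    f_max[order] = f_max_ordered
    score = (f_max - f) / f_max
    return pd.DataFrame(
        {
            "gene_index": np.arange(X.n_genes),
            "f": f,
            "f_max": f_max,
            "score": score,
        },
        index=list(X.gene_names),
    )


def select_variable_genes(
    table: pd.DataFrame,
    abs_threshold: float = 0.15,
    sd_multiplier: float = 6.0,
) -> np.ndarray:
    """Boolean selection mask over the score table's genes.

    A gene is selected when its dropout score is strictly greater than
    ``abs_threshold`` OR at least ``sd_multiplier`` population standard
    deviations above the mean score (inclusive).  When the score standard
    deviation is exactly zero, the SD rule is suppressed (it would otherwise
    select every gene in the all-tied degenerate case).
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    scores = table["score"].to_numpy()
    selected = scores > abs_threshold
    sd = scores.std()
    if sd > 0:
        selected |= scores >= scores.mean() + sd_multiplier * sd
    return selected
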