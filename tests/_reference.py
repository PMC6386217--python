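"""Independent reference implementations used as oracles.

Everything here is deliberately naive: dense arrays, explicit loops over
every (cell, gene, factor) triple, and a fully materialized N x M x K phi
tensor.  The production code must agree with these on small instances; the
oracles never call into the production update code.
"""

import numpy as np
from scipy.special import digamma, gammaln


def dense_phi(gamma_shape, gamma_rate, lambda_shape, lambda_rate):
    """phi[i, g, k] from the explicit formula, normalized per (i, g)."""
    N, K = gamma_shape.shape
    M = lambda_shape.shape[0]
    phi = np.empty((N, M, K))
    for i in range(N):
        for g in range(M):
            w = np.empty(K)
            for k in range(K):
                w[k] = (
                    digamma(gamma_shape[i, k])
                    - np.log(gamma_rate[i, k])
                    + digamma(lambda_shape[g, k])
                    - np.log(lambda_rate[g, k])
                )
            w = np.exp(w - w.max())
            phi[i, g] = w / w.sum()
    return phi


def dense_sweep(state, X_dense, phi_full, hyper):
    """One CAVI sweep with triple loops and the full phi tensor.

    Mutates nothing; returns a dict of new arrays plus the next sweep's phi
    tensor.  Update order matches the algorithm: gene block (lambda shapes,
    lambda rates, tau rates), then cell block (gamma shapes, gamma rates,
    kappa rates) using the same phi, then phi from the updated state.
    """
    N, M = X_dense.shape
    K = hyper.K
    gs, gr = state.gamma_shape.copy(), state.gamma_rate.copy()
    ls, lr = state.lambda_shape.copy(), state.lambda_rate.copy()
    ks, kr = state.kappa_shape.copy(), state.kappa_rate.copy()
    ts, tr = state.tau_shape.copy(), state.tau_rate.copy()

    new_ls = np.empty((M, K))
    new_lr = np.empty((M, K))
    new_tr = np.empty(M)
    for g in range(M):
        for k in range(K):
            acc = 0.0
            for i in range(N):
                acc += X_dense[i, g] * phi_full[i, g, k]
            new_ls[g, k] = hyper.c + acc
            acc = 0.0
            for i in range(N):
                acc += gs[i, k] / gr[i, k]
            new_lr[g, k] = ts[g] / tr[g] + acc
        new_tr[g] = hyper.d_prime + sum(
            new_ls[g, k] / new_lr[g, k] for k in range(K)
        )

    new_gs = np.empty((N, K))
    new_gr = np.empty((N, K))
    new_kr = np.empty(N)
    for i in range(N):
        for k in range(K):
            acc = 0.0
            for g in range(M):
                acc += X_dense[i, g] * phi_full[i, g, k]
            new_gs[i, k] = hyper.a + acc
            acc = 0.0
            for g in range(M):
                acc += new_ls[g, k] / new_lr[g, k]
            new_gr[i, k] = ks[i] / kr[i] + acc
        new_kr[i] = hyper.b_prime + sum(
            new_gs[i, k] / new_gr[i, k] for k in range(K)
        )

    next_phi = dense_phi(new_gs, new_gr, new_ls, new_lr)
    return {
        "lambda_shape": new_ls,
        "lambda_rate": new_lr,
        "tau_rate": new_tr,
        "gamma_shape": new_gs,
        "gamma_rate": new_gr,
        "kappa_rate": new_kr,
        "phi": next_phi,
    }


def phi_full_from_entry_block(X, phi_block, K):
    """Scatter a per-nonzero-entry phi block into a dense N x M x K tensor.

    Entries at zero coordinates are filled uniformly; they multiply x = 0 in
    every shape sum, so their value is immaterial.
    """
    full = np.full((X.n_cells, X.n_genes, K), 1.0 / K)
    full[X.rows, X.cols] = phi_block
    return full


def poisson_logpmf(x, lam):
    return x * np.log(lam) - lam - gammaln(x + 1.0)


def brute_force_ks(a, b):
    """sup |ECDF_a - ECDF_b| scanned over the pooled support."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    support = np.concatenate([a, b])
    best = 0.0
    for v in support:
        d = abs(np.mean(a <= v) - np.mean(b <= v))
        best = max(best, d)
    return best


def brute_force_window_max(values, window):
    """Centred truncated-window maximum by explicit index arithmetic."""
    values = np.asarray(values, dtype=float)
    n = values.size
    # even windows take the extra element on the left
    half_lo = window // 2
    half_hi = (window - 1) // 2
    out = np.empty(n)
    for j in range(n):
        lo = max(0, j - half_lo)
        hi = min(n, j + half_hi + 1)
        out[j] = values[lo:hi].max()
    return out
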