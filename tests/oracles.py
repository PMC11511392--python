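"""Independent numerical oracles used to cross-check the fusion solvers.

These deliberately take different computational routes from the package
implementation (whitened SVD for CCA; a dense non-symmetric generalized
eigensolver for the multiset problem) so agreement is meaningful.
"""

import numpy as np
import scipy.linalg as sla


def _inv_sqrt(S):
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 1e-12, None)
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def cca_whitened_svd(X, Y, k):
    """CCA via SVD of the whitened cross-covariance.

    Returns (wx, wy, correlations) with directions normalized to unit
    projected variance.
    """
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    n = X.shape[0]
    Sxx, Syy = X.T @ X / n, Y.T @ Y / n
    Sxy = X.T @ Y / n
    Wx, Wy = _inv_sqrt(Sxx), _inv_sqrt(Syy)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    wx = Wx @ U[:, :k]
    wy = Wy @ Vt[:k].T
    return wx, wy, s[:k]


def mcca_dense_eig(Xs, k, ridge=1e-8):
    """Brute-force multiset solution via scipy's dense non-symmetric
    generalized eigensolver on the block matrices.

    Returns (eigenvalues, per-set direction blocks) normalized to
    ``sum_i a_i' S_ii a_i = 1`` with the sign convention of the package
    (largest-magnitude coefficient positive).
    """
    Xs = [X - X.mean(axis=0) for X in Xs]
    n = Xs[0].shape[0]
    m = len(Xs)
    S = [[Xs[i].T @ Xs[j] / n for j in range(m)] for i in range(m)]
    dims = [X.shape[1] for X in Xs]
    A = np.block([[S[i][j] for j in range(m)] for i in range(m)])
    B = sla.block_diag(*[
        S[i][i] + ridge * np.trace(S[i][i]) / dims[i] * np.eye(dims[i])
        for i in range(m)
    ])
    evals, evecs = sla.eig(A, B)
    assert np.max(np.abs(evals.imag)) < 1e-6
    order = np.argsort(evals.real)[::-1][:k]
    V = evecs[:, order].real
    parts, lo = [], 0
    for d in dims:
        parts.append(V[lo:lo + d, :])
        lo += d
    lam = np.empty(k)
    for j in range(k):
        norm2 = sum(parts[i][:, j] @ S[i][i] @ parts[i][:, j] for i in range(m))
        scale = np.sqrt(norm2)
        for i in range(m):
            parts[i][:, j] /= scale
        stacked = np.concatenate([p[:, j] for p in parts])
        i_max = int(np.argmax(np.abs(stacked)))
        if stacked[i_max] < 0:
            for i in range(m):
                parts[i][:, j] = -parts[i][:, j]
        lam[j] = sum(parts[i][:, j] @ S[i][jj] @ parts[jj][:, j]
                     for i in range(m) for jj in range(m))
    return lam, parts
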