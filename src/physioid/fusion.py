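"""Dimensionality reduction and multi-modal feature fusion.

Implements, from first principles on top of dense symmetric eigensolvers:

* **PCA** — eigendecomposition of the sample covariance ``J = X'X / n`` of
  the mean-centered data, keeping the leading components by count or by
  cumulative contribution rate.
* **LDA** — the multi-class discriminant: top eigenvectors of
  ``inv(Sw + eps I) Sb`` where Sw/Sb are the within/between-class scatter
  matrices and ``eps = 1e-6 trace(Sw)/d`` is a stabilizing ridge.
* **CCA / MCCA** — (multiset) canonical correlation as a block generalized
  eigenproblem: the full cross-covariance block matrix ``S = [S_ij]`` on
  the left against the block-diagonal ``diag(S_ii)`` on the right, under
  the constraint ``sum_i a_i' S_ii a_i = 1``.  For two sets the leading
  eigenvalue is ``1 + rho`` with ``rho`` the first canonical correlation.
* **Serial / parallel fusion** — concatenation, and the complex composite
  ``z = x + i y`` materialized as (real, imaginary) channels or modulus.

The default cascade standardizes each modality, reduces it with PCA to 10
and LDA to 6 dimensions, then fuses the three 6-D sets with MCCA (k = 6)
and concatenates the projections into one 18-D fused representation.  All
transforms are fitted on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PcaModel", "LdaModel", "CcaModel", "MccaModel", "FusedDataset",
    "Standardizer", "FusionConfig", "FusionPipeline",
    "pca_fit", "contribution_report", "lda_fit", "cca_fit", "mcca_fit",
    "serial_fuse", "parallel_fuse", "fuse_pipeline",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples-by-features array")
    return X


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude coefficient of each column positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature z-scoring with training statistics."""

    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None

    def fit(self, X) -> "Standardizer":
        X = _as_array(X)
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        # Constant features pass through un-scaled rather than exploding.
        self.std_ = np.where(std < 1e-12, 1.0, std)
        return self

    def transform(self, X) -> np.ndarray:
        return (_as_array(X) - self.mean_) / self.std_

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    mean_: np.ndarray                 # sample mean x-bar
    components: np.ndarray            # (d, k) orthonormal eigenvectors of J
    eigenvalues: np.ndarray           # all d eigenvalues, descending
    contribution_rates: np.ndarray    # lambda_i / sum(lambda), all d
    cumulative_rates: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def transform(self, X) -> np.ndarray:
        return (_as_array(X) - self.mean_) @ self.components

    def reconstruct(self, Y) -> np.ndarray:
        return np.asarray(Y) @ self.components.T + self.mean_


def pca_fit(X, k: int | None = None, cum_threshold: float | None = None) -> PcaModel:
    """Principal component analysis of mean-centered data.

    Exactly one of ``k`` (component count) or ``cum_threshold`` (smallest k
    whose cumulative contribution rate reaches the threshold) selects the
    retained dimensionality; with neither, all components are kept.
    """
    X = _as_array(X)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if k is not None and not 1 <= k <= d:
        raise ValueError(f"k must lie in [1, {d}], got {k}")
    mean = X.mean(axis=0)
    Xc = X - mean
    J = Xc.T @ Xc / n
    evals, evecs = np.linalg.eigh(J)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    total = evals.sum()
    rates = evals / total if total > 0 else np.full(d, 1.0 / d)
    cum = np.cumsum(rates)
    if k is None:
        if cum_threshold is not None:
            if not 0 < cum_threshold <= 1:
                raise ValueError("cum_threshold must lie in (0, 1]")
            k = int(np.searchsorted(cum, cum_threshold - 1e-12) + 1)
            k = min(k, d)
        else:
            k = d
    return PcaModel(mean_=mean, components=evecs[:, :k], eigenvalues=evals,
                    contribution_rates=rates, cumulative_rates=cum)


def contribution_report(model: PcaModel) -> pd.DataFrame:
    """Per-component and cumulative contribution rates (all components)."""
    return pd.DataFrame({
        "component": np.arange(1, model.eigenvalues.size + 1),
        "eigenvalue": model.eigenvalues,
        "contribution_rate": model.contribution_rates,
        "cumulative_rate": model.cumulative_rates,
    })


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    Sw: np.ndarray
    Sb: np.ndarray
    class_means: dict
    W: np.ndarray               # (d, k) projection matrix
    eigenvalues: np.ndarray     # Rayleigh quotients w'Sb w / w'Sw w
    ridge: float

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def transform(self, X) -> np.ndarray:
        return _as_array(X) @ self.W


def lda_fit(X, labels, k: int) -> LdaModel:
    """Fisher discriminant projection to ``k <= n_classes - 1`` dimensions.

    The within-class scatter is ridge-regularized with
    ``eps = 1e-6 trace(Sw)/d``; reported eigenvalues are the exact Rayleigh
    quotients of the unridged scatter matrices at the solved directions.
    """
    X = _as_array(X)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n, d = X.shape
    if classes.size < 2:
        raise ValueError("LDA needs at least 2 classes")
    if not 1 <= k <= classes.size - 1:
        raise ValueError(
            f"k must lie in [1, n_classes - 1] = [1, {classes.size - 1}] "
            f"(rank bound of the between-class scatter), got {k}"
        )
    overall = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    means = {}
    for c in classes:
        Xi = X[labels == c]
        ui = Xi.mean(axis=0)
        means[c] = ui
        Z = Xi - ui
        Sw += Z.T @ Z
        diff = (ui - overall)[:, None]
        Sb += Xi.shape[0] * (diff @ diff.T)
    eps = 1e-6 * np.trace(Sw) / d
    evals, evecs = sla.eigh(Sb, Sw + eps * np.eye(d))
    order = np.argsort(evals)[::-1][:k]
    W = _fix_signs(evecs[:, order])
    rayleigh = np.array([
        (w @ Sb @ w) / (w @ Sw @ w) for w in W.T
    ])
    return LdaModel(Sw=Sw, Sb=Sb, class_means=means, W=W,
                    eigenvalues=rayleigh, ridge=eps)


# ---------------------------------------------------------------------------
# CCA / MCCA
# ---------------------------------------------------------------------------

def _covariance_blocks(Xs: list[np.ndarray]):
    n = Xs[0].shape[0]
    means = [X.mean(axis=0) for X in Xs]
    Xc = [X - m for X, m in zip(Xs, means)]
    S = [[Xc[i].T @ Xc[j] / n for j in range(len(Xs))] for i in range(len(Xs))]
    return means, Xc, S


def _solve_block_gevp(S, ridge: float, k: int):
    """Generalized eigenproblem of the multiset canonical criterion.

    Left: full block covariance matrix [S_ij]; right: block-diagonal
    diag(S_ii), each block ridge-regularized with
    ``eps_i = ridge * trace(S_ii)/d_i``.
    """
    n_sets = len(S)
    dims = [S[i][i].shape[0] for i in range(n_sets)]
    A = np.block([[S[i][j] for j in range(n_sets)] for i in range(n_sets)])
    A = 0.5 * (A + A.T)
    B_blocks = []
    for i in range(n_sets):
        eps = ridge * np.trace(S[i][i]) / dims[i]
        B_blocks.append(S[i][i] + eps * np.eye(dims[i]))
    B = sla.block_diag(*B_blocks)
    try:
        evals, evecs = sla.eigh(A, B)
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular self-covariance block despite ridge "
            f"{ridge!r}; increase the mcca ridge"
        ) from exc
    order = np.argsort(evals)[::-1][:k]
    return evals[order], _fix_signs(evecs[:, order]), dims


def _split_rows(V: np.ndarray, dims: list[int]):
    out, lo = [], 0
    for d in dims:
        out.append(V[lo:lo + d, :])
        lo += d
    return out


@dataclass
class CcaModel:
    means: list
    wx: np.ndarray              # (dx, k) directions for set 1
    wy: np.ndarray              # (dy, k) directions for set 2
    correlations: np.ndarray    # canonical correlations, nonincreasing

    def transform(self, X, Y):
        X, Y = _as_array(X), _as_array(Y)
        return (X - self.means[0]) @ self.wx, (Y - self.means[1]) @ self.wy


def cca_fit(X, Y, k: int) -> CcaModel:
    """Canonical correlation analysis of two feature sets.

    Directions are normalized to unit projected variance per set; canonical
    correlations are reported in [0, 1], nonincreasing.
    """
    X, Y = _as_array(X), _as_array(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"row mismatch: {X.shape[0]} vs {Y.shape[0]} samples"
        )
    if not 1 <= k <= min(X.shape[1], Y.shape[1]):
        raise ValueError(f"k must lie in [1, {min(X.shape[1], Y.shape[1])}]")
    means, Xc, S = _covariance_blocks([X, Y])
    evals, V, dims = _solve_block_gevp(S, ridge=1e-10, k=k)
    wx, wy = _split_rows(V, dims)
    # Unit projected variance per set.
    for w, Sii in ((wx, S[0][0]), (wy, S[1][1])):
        for j in range(w.shape[1]):
            scale = np.sqrt(w[:, j] @ Sii @ w[:, j])
            if scale > 0:
                w[:, j] /= scale
    corr = np.clip(evals - 1.0, 0.0, 1.0)
    return CcaModel(means=means, wx=wx, wy=wy, correlations=corr)


@dataclass
class MccaModel:
    """Fitted multiset canonical correlation transform.

    ``directions[i]`` holds the k projection directions of set i;
    ``eigenvalues`` are the generalized eigenvalues lambda (Rayleigh
    quotients of the unridged blocks); the per-direction normalization is
    ``sum_i a_i' S_ii a_i = 1``.
    """

    means: list
    directions: list            # n_sets arrays of shape (d_i, k)
    eigenvalues: np.ndarray
    S: list                     # full covariance blocks S[i][j]
    ridge: float
    combine: str = "concat"     # "concat" | "sum"

    @property
    def k(self) -> int:
        return self.directions[0].shape[1]

    def transform_sets(self, Xs) -> list[np.ndarray]:
        Xs = [_as_array(X) for X in Xs]
        return [(X - m) @ a for X, m, a in zip(Xs, self.means, self.directions)]

    def transform(self, Xs) -> np.ndarray:
        proj = self.transform_sets(Xs)
        if self.combine == "sum":
            return np.sum(proj, axis=0)
        return np.hstack(proj)


def mcca_fit(Xs, k: int, ridge: float = 1e-8, combine: str = "concat") -> MccaModel:
    """Multiset canonical correlation analysis across n >= 2 feature sets.

    Solves the symmetric-definite generalized eigenproblem of the multiset
    canonical criterion (full block covariance matrix against the
    block-diagonal self-covariances), retains the top ``k`` eigenvectors,
    splits each into per-set directions and rescales them to satisfy
    ``sum_i a_i' S_ii a_i = 1`` exactly (unridged blocks).
    """
    Xs = [_as_array(X) for X in Xs]
    if len(Xs) < 2:
        raise ValueError("MCCA needs at least 2 sets")
    n = Xs[0].shape[0]
    for X in Xs[1:]:
        if X.shape[0] != n:
            raise ValueError("all sets must have equal row counts")
    total_dim = sum(X.shape[1] for X in Xs)
    if not 1 <= k <= total_dim:
        raise ValueError(f"k must lie in [1, {total_dim}]")
    if combine not in ("concat", "sum"):
        raise ValueError(f"unknown combine mode {combine!r}")
    means, Xc, S = _covariance_blocks(Xs)
    evals, V, dims = _solve_block_gevp(S, ridge=ridge, k=k)
    parts = _split_rows(V, dims)
    # Exact normalization against the raw (unridged) self-covariances, and
    # eigenvalues re-expressed as Rayleigh quotients of the raw blocks.
    n_sets = len(Xs)
    lam = np.empty(k)
    for j in range(k):
        norm2 = sum(parts[i][:, j] @ S[i][i] @ parts[i][:, j] for i in range(n_sets))
        if norm2 <= 0:
            raise np.linalg.LinAlgError(
                "degenerate direction (zero projected variance); "
                "increase the mcca ridge"
            )
        scale = np.sqrt(norm2)
        for i in range(n_sets):
            parts[i][:, j] /= scale
        num = sum(parts[i][:, j] @ S[i][jj] @ parts[jj][:, j]
                  for i in range(n_sets) for jj in range(n_sets))
        lam[j] = num
    return MccaModel(means=means, directions=parts, eigenvalues=lam,
                     S=S, ridge=ridge, combine=combine)


# ---------------------------------------------------------------------------
# Serial / parallel fusion
# ---------------------------------------------------------------------------

@dataclass
class FusedDataset:
    X: np.ndarray
    labels: np.ndarray | None
    fusion_method: str
    source_dims: tuple

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def _check_rows(arrays):
    n = arrays[0].shape[0]
    for a in arrays[1:]:
        if a.shape[0] != n:
            raise ValueError(
                f"row mismatch across fused sets: {[x.shape[0] for x in arrays]}"
            )


def serial_fuse(*Xs, labels=None) -> FusedDataset:
    """Row-wise concatenation (head-to-tail feature merge)."""
    arrays = [_as_array(X) for X in Xs]
    _check_rows(arrays)
    return FusedDataset(
        X=np.hstack(arrays),
        labels=None if labels is None else np.asarray(labels),
        fusion_method="serial",
        source_dims=tuple(a.shape[1] for a in arrays),
    )


def parallel_fuse(X, Y, labels=None, mode: str = "channels") -> FusedDataset:
    """Complex composite z = x + i y of two feature sets.

    The shorter set is zero-padded to the longer's dimension.  ``mode``
    selects the real-valued materialization for downstream classifiers:
    ``"channels"`` stacks the (real, imaginary) parts side by side;
    ``"modulus"`` takes |z| per coordinate.
    """
    X, Y = _as_array(X), _as_array(Y)
    _check_rows([X, Y])
    d = max(X.shape[1], Y.shape[1])
    Xp = np.pad(X, ((0, 0), (0, d - X.shape[1])))
    Yp = np.pad(Y, ((0, 0), (0, d - Y.shape[1])))
    if mode == "channels":
        fused = np.hstack([Xp, Yp])
    elif mode == "modulus":
        fused = np.sqrt(Xp ** 2 + Yp ** 2)
    else:
        raise ValueError(f"unknown parallel mode {mode!r}")
    return FusedDataset(
        X=fused,
        labels=None if labels is None else np.asarray(labels),
        fusion_method="parallel",
        source_dims=(X.shape[1], Y.shape[1]),
    )


# ---------------------------------------------------------------------------
# PCA -> LDA -> MCCA cascade
# ---------------------------------------------------------------------------

@dataclass
class FusionConfig:
    pca_k: int = 10
    pca_cum_threshold: float | None = None   # overrides pca_k when set
    lda_k: int = 6
    mcca_k: int = 6
    mcca_ridge: float = 1e-8
    combine: str = "concat"


class FusionPipeline:
    """Standardize -> PCA -> LDA per modality, then MCCA across modalities.

    All statistics are fitted on the training rows handed to :meth:`fit`
    and merely applied by :meth:`transform`, so test rows never leak into
    the fitted transforms.
    """

    def __init__(self, config: FusionConfig | None = None):
        self.config = config or FusionConfig()
        self.scalers_: dict = {}
        self.pca_: dict = {}
        self.lda_: dict = {}
        self.mcca_: MccaModel | None = None
        self.modalities_: list | None = None

    def fit(self, matrices: dict, labels) -> "FusionPipeline":
        cfg = self.config
        labels = np.asarray(labels)
        self.modalities_ = list(matrices)
        reduced = []
        for mod in self.modalities_:
            X = _as_array(matrices[mod])
            if X.shape[0] != labels.size:
                raise ValueError(f"labels misaligned with modality {mod}")
            scaler = Standardizer().fit(X)
            Z = scaler.transform(X)
            pca = (pca_fit(Z, cum_threshold=cfg.pca_cum_threshold)
                   if cfg.pca_cum_threshold is not None
                   else pca_fit(Z, k=cfg.pca_k))
            P = pca.transform(Z)
            lda = lda_fit(P, labels, k=cfg.lda_k)
            reduced.append(lda.transform(P))
            self.scalers_[mod], self.pca_[mod], self.lda_[mod] = scaler, pca, lda
        self.mcca_ = mcca_fit(reduced, k=cfg.mcca_k, ridge=cfg.mcca_ridge,
                              combine=cfg.combine)
        return self

    def _reduce(self, matrices: dict) -> list[np.ndarray]:
        out = []
        for mod in self.modalities_:
            Z = self.scalers_[mod].transform(_as_array(matrices[mod]))
            out.append(self.lda_[mod].transform(self.pca_[mod].transform(Z)))
        return out

    def transform(self, matrices: dict) -> np.ndarray:
        if self.mcca_ is None:
            raise ValueError("pipeline is not fitted")
        return self.mcca_.transform(self._reduce(matrices))


def fuse_pipeline(train_matrices: dict, train_labels, test_matrices: dict | None = None,
                  config: FusionConfig | None = None):
    """Fit the PCA->LDA->MCCA cascade on training rows and apply it.

    Returns ``(train_fused, test_fused, pipeline)`` where the fused sets
    are :class:`FusedDataset` (``test_fused`` is None without test rows).
    """
    pipe = FusionPipeline(config).fit(train_matrices, train_labels)
    dims = tuple(pipe.lda_[m].k for m in pipe.modalities_)
    train = FusedDataset(pipe.transform(train_matrices),
                         np.asarray(train_labels), "mcca", dims)
    test = None
    if test_matrices is not None:
        test = FusedDataset(pipe.transform(test_matrices), None, "mcca", dims)
    return train, test, pipe
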