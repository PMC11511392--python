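"""SVM identification experiments.

Subjects are identified with a one-vs-one multiclass SVM whose kernel
hyper-parameters (C and gamma, or degree for the polynomial kernel) are
chosen by cross-validated grid search on the training split only.  The
experiment designs mirror a 7:3 stratified split repeated 10 times:

* ``single`` — one modality, raw 20-D features, polynomial kernel;
* ``dual`` — two modalities fused by serial / parallel / CCA / PCA+CCA;
* ``tri`` — the PCA -> LDA -> MCCA cascade over all three modalities.

Accuracy is the pooled fraction of correctly identified test samples
(TP+TN over all counts in the two-class formulation); per-class one-vs-rest
confusion tallies are kept alongside.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix
from .fusion import (FusionConfig, FusionPipeline, Standardizer, cca_fit,
                     parallel_fuse, pca_fit, serial_fuse)

logger = logging.getLogger(__name__)

__all__ = [
    "SvmConfig", "SvmModel", "ConfusionCounts", "ExperimentDesign",
    "ExperimentResult", "split_dataset", "train_svm", "evaluate",
    "run_experiment",
]

_C_GRID = tuple(float(2.0 ** e) for e in range(-5, 17, 2))       # 2^-5 .. 2^15
_GAMMA_GRID = tuple(float(2.0 ** e) for e in range(-15, 5, 2))   # 2^-15 .. 2^3


@dataclass
class SvmConfig:
    """Kernel, penalty grid and cross-validation settings."""

    kernel: str = "rbf"            # linear | poly | rbf | sigmoid
    C_grid: tuple = _C_GRID
    gamma_grid: tuple = _GAMMA_GRID
    degree: int = 3                # polynomial kernel degree
    coef0: float = 0.0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "poly", "rbf", "sigmoid"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not self.C_grid or any(c <= 0 for c in self.C_grid):
            raise ValueError("C grid must be non-empty and positive")
        if not self.gamma_grid:
            raise ValueError("gamma grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SvmModel:
    estimator: Pipeline            # fitted scaler + SVC
    best_params: dict
    cv_accuracy: float
    n_features: int
    classes: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the "
                f"model's {self.n_features}"
            )
        return self.estimator.predict(X)


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest tallies plus pooled counts.

    In the pooled multiclass view every correctly identified sample is a
    true decision (TP+TN of the binary formulation) and every error counts
    once as a false accept (FP) and once as a false reject (FN) of the
    classes involved, so the accuracy formula (TP+TN)/(TP+TN+FP+FN) reduces
    to correct/total.
    """

    per_class: dict                 # label -> dict(tp, fp, fn, tn)
    n_correct: int
    n_total: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def split_dataset(labels, ratio: float = 0.7, seed: int = 0):
    """Stratified train/test split at ``ratio`` (train fraction).

    The per-class test count is ``floor(n_c * (1 - ratio))`` so a
    25-class, 20-per-class set at 7:3 yields exactly 350/150.
    Deterministic per seed; returns (train_idx, test_idx).
    """
    labels = np.asarray(labels)
    if not 0 < ratio < 1:
        raise ValueError(f"split ratio must lie strictly in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        n_test = int(np.floor(idx.size * (1 - ratio)))
        if n_test == 0 or n_test == idx.size:
            raise ValueError(
                f"ratio {ratio} leaves class {c!r} without a train or test sample"
            )
        perm = rng.permutation(idx)
        test.extend(perm[:n_test])
        train.extend(perm[n_test:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def train_svm(X, y, cfg: SvmConfig | None = None) -> SvmModel:
    """Grid-searched one-vs-one SVM on the training set only."""
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")
    est = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel=cfg.kernel, degree=cfg.degree, coef0=cfg.coef0,
                    decision_function_shape="ovo", cache_size=256)),
    ])
    grid = {"svc__C": list(cfg.C_grid)}
    if cfg.kernel != "linear":
        grid["svc__gamma"] = list(cfg.gamma_grid)
    folds = min(cfg.cv_folds, int(np.min(np.bincount(
        np.searchsorted(np.unique(y), y)))))
    folds = max(folds, 2)
    search = GridSearchCV(est, grid, cv=StratifiedKFold(n_splits=folds),
                          n_jobs=1, scoring="accuracy", refit=True)
    search.fit(X, y)
    logger.info("SVM grid search: best %s (CV accuracy %.4f)",
                search.best_params_, search.best_score_)
    return SvmModel(
        estimator=search.best_estimator_,
        best_params={k.replace("svc__", ""): v
                     for k, v in search.best_params_.items()},
        cv_accuracy=float(search.best_score_),
        n_features=X.shape[1],
        classes=np.unique(y),
    )


def evaluate(model: SvmModel, X, y) -> tuple[ConfusionCounts, float]:
    """Confusion tallies and pooled accuracy on a labeled test set."""
    y = np.asarray(y)
    pred = model.predict(X)
    per_class = {}
    for c in np.unique(np.concatenate([y, pred])):
        tp = int(np.sum((pred == c) & (y == c)))
        fp = int(np.sum((pred == c) & (y != c)))
        fn = int(np.sum((pred != c) & (y == c)))
        tn = int(y.size - tp - fp - fn)
        per_class[c] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    counts = ConfusionCounts(
        per_class=per_class,
        n_correct=int(np.sum(pred == y)),
        n_total=int(y.size),
    )
    return counts, counts.accuracy


@dataclass
class ExperimentDesign:
    """Which modalities participate and how they are fused.

    ``kind`` is ``"single"`` (one modality, no fusion), ``"dual"``
    (``method`` in serial/parallel/cca/pca+cca) or ``"tri"`` (the
    PCA->LDA->MCCA cascade).
    """

    kind: str
    modalities: tuple
    method: str | None = None

    def __post_init__(self) -> None:
        self.modalities = tuple(str(m).upper() for m in self.modalities)
        if self.kind == "single":
            if len(self.modalities) != 1:
                raise ValueError("single design takes exactly one modality")
        elif self.kind == "dual":
            if len(self.modalities) != 2:
                raise ValueError("dual design takes exactly two modalities")
            if self.method not in ("serial", "parallel", "cca", "pca+cca"):
                raise ValueError(f"unknown dual fusion method {self.method!r}")
        elif self.kind == "tri":
            if len(self.modalities) != 3:
                raise ValueError("tri design takes exactly three modalities")
            if self.method not in (None, "mcca"):
                raise ValueError(f"unknown tri fusion method {self.method!r}")
        else:
            raise ValueError(f"unknown design kind {self.kind!r}")

    @property
    def name(self) -> str:
        tag = "+".join(self.modalities)
        return f"{self.kind}({tag})" + (f"[{self.method}]" if self.method else "")


@dataclass
class ExperimentResult:
    design: str
    per_repeat_accuracy: list
    mean_accuracy: float
    per_subject_accuracy: dict     # label -> pooled accuracy over repeats
    best_params: list              # per repeat
    config: dict
    seeds: list

    def summary(self) -> str:
        accs = ", ".join(f"{a:.4f}" for a in self.per_repeat_accuracy)
        return (f"{self.design}: mean accuracy {self.mean_accuracy:.4f} "
                f"over {len(self.per_repeat_accuracy)} repeats [{accs}]")


def _dual_features(design, Xs, labels_train, train_idx, test_idx, fusion_cfg):
    """Fit the dual-modality fusion on training rows; return train/test X."""
    Xa, Xb = Xs
    if design.method == "serial":
        return (serial_fuse(Xa[train_idx], Xb[train_idx]).X,
                serial_fuse(Xa[test_idx], Xb[test_idx]).X)
    if design.method == "parallel":
        return (parallel_fuse(Xa[train_idx], Xb[train_idx]).X,
                parallel_fuse(Xa[test_idx], Xb[test_idx]).X)
    k = min(fusion_cfg.pca_k, Xa.shape[1], Xb.shape[1])
    sa = Standardizer().fit(Xa[train_idx])
    sb = Standardizer().fit(Xb[train_idx])
    A_tr, B_tr = sa.transform(Xa[train_idx]), sb.transform(Xb[train_idx])
    A_te, B_te = sa.transform(Xa[test_idx]), sb.transform(Xb[test_idx])
    if design.method == "pca+cca":
        pa = pca_fit(A_tr, k=min(fusion_cfg.pca_k, A_tr.shape[1]))
        pb = pca_fit(B_tr, k=min(fusion_cfg.pca_k, B_tr.shape[1]))
        A_tr, B_tr = pa.transform(A_tr), pb.transform(B_tr)
        A_te, B_te = pa.transform(A_te), pb.transform(B_te)
        k = min(k, A_tr.shape[1], B_tr.shape[1])
    cca = cca_fit(A_tr, B_tr, k=k)
    U_tr, V_tr = cca.transform(A_tr, B_tr)
    U_te, V_te = cca.transform(A_te, B_te)
    return np.hstack([U_tr, V_tr]), np.hstack([U_te, V_te])


def run_experiment(
    matrices: dict,
    design: ExperimentDesign,
    n_repeats: int = 10,
    seed: int = 0,
    svm: SvmConfig | None = None,
    fusion: FusionConfig | None = None,
    ratio: float = 0.7,
    shuffle_labels: bool = False,
) -> ExperimentResult:
    """Repeated stratified split -> fit fusion on train -> SVM -> evaluate.

    ``matrices`` maps modality name to an aligned
    :class:`~physioid.features.FeatureMatrix` (identical label vectors).
    The split of repeat ``r`` depends only on (seed, r, labels), so runs
    with different designs but the same seed are paired.
    ``shuffle_labels=True`` permutes the labels per repeat (chance-level
    control).
    """
    fusion = fusion or FusionConfig()
    for mod in design.modalities:
        if mod not in matrices:
            raise ValueError(f"design needs modality {mod} but it is missing")
    mats = {m: matrices[m] for m in design.modalities}
    labels0 = np.asarray(next(iter(mats.values())).labels)
    for m, fm in mats.items():
        if not np.array_equal(np.asarray(fm.labels), labels0):
            raise ValueError(f"labels of modality {m} are misaligned")
    if svm is None:
        svm = SvmConfig(kernel="poly" if design.kind == "single" else "rbf")

    per_repeat, best_params, seeds = [], [], []
    subj_correct: dict = {}
    subj_total: dict = {}
    for r in range(n_repeats):
        rng = np.random.default_rng([seed, r])
        split_seed = int(rng.integers(0, 2 ** 31 - 1))
        labels = labels0
        if shuffle_labels:
            labels = rng.permutation(labels0)
        train_idx, test_idx = split_dataset(labels, ratio=ratio, seed=split_seed)
        y_tr, y_te = labels[train_idx], labels[test_idx]

        if design.kind == "single":
            X = mats[design.modalities[0]].X
            X_tr, X_te = X[train_idx], X[test_idx]
        elif design.kind == "dual":
            Xs = [mats[m].X for m in design.modalities]
            X_tr, X_te = _dual_features(design, Xs, y_tr, train_idx, test_idx, fusion)
        else:
            pipe = FusionPipeline(fusion).fit(
                {m: mats[m].X[train_idx] for m in design.modalities}, y_tr)
            X_tr = pipe.transform({m: mats[m].X[train_idx]
                                   for m in design.modalities})
            X_te = pipe.transform({m: mats[m].X[test_idx]
                                   for m in design.modalities})

        model = train_svm(X_tr, y_tr, svm)
        counts, acc = evaluate(model, X_te, y_te)
        per_repeat.append(acc)
        best_params.append(model.best_params)
        seeds.append(split_seed)
        pred = model.predict(X_te)
        for c in np.unique(y_te):
            mask = y_te == c
            subj_correct[c] = subj_correct.get(c, 0) + int(np.sum(pred[mask] == c))
            subj_total[c] = subj_total.get(c, 0) + int(np.sum(mask))
        logger.info("%s repeat %d: accuracy %.4f", design.name, r, acc)

    per_subject = {c: subj_correct[c] / subj_total[c] for c in sorted(subj_total)}
    return ExperimentResult(
        design=design.name,
        per_repeat_accuracy=per_repeat,
        mean_accuracy=float(np.mean(per_repeat)),
        per_subject_accuracy=per_subject,
        best_params=best_params,
        config={"svm": asdict(svm), "fusion": asdict(fusion),
                "ratio": ratio, "n_repeats": n_repeats, "seed": seed,
                "shuffle_labels": shuffle_labels},
        seeds=seeds,
    )
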