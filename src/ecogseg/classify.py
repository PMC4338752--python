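"""mRMR feature selection and Ledoit-Wolf shrinkage LDA with 5-fold CV.

The decoder is a regularized linear discriminant: the pooled within-class
covariance is shrunk toward a scaled identity with the Ledoit-Wolf optimal
intensity, giving a well-conditioned estimate even when the number of
time-bin features rivals the number of phoneme epochs.  Ahead of the fit,
minimum-redundancy-maximum-relevance (mRMR, MID/difference form) greedily
picks features that carry mutual information about the +/- label while
avoiding features redundant with those already chosen; mutual information
is computed on 3-level quantile-discretized features.

Feature selection and classifier training happen strictly inside each
training fold of the (stratified) 5-fold cross-validation; held-out decision
values are scored with ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf
from sklearn.model_selection import StratifiedKFold

from .stats import roc_auc

__all__ = [
    "TrainedModel",
    "CVResult",
    "discretize_quantile",
    "mutual_information",
    "mrmr_select",
    "ledoit_wolf_cov",
    "train_rlda",
    "decision_values",
    "cross_validate",
    "dump_selected_features",
]


@dataclass
class TrainedModel:
    weights: np.ndarray  # direction in the selected feature space
    bias: float
    shrinkage: float  # Ledoit-Wolf lambda in [0, 1]
    selected: np.ndarray  # indices into the full feature space, mRMR order


@dataclass
class CVResult:
    fold_scores: np.ndarray  # held-out decision value per observation
    fold_assignment: np.ndarray  # observation -> fold index
    fold_aucs: np.ndarray
    auc_mean: float
    selected_per_fold: list


def discretize_quantile(X: np.ndarray, levels: int = 3) -> np.ndarray:
    """Per-column quantile discretization into ``levels`` integer bins.

    Constant columns map to a single level (and hence zero mutual
    information with anything).
    """
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape, dtype=np.int64)
    qs = np.linspace(0, 1, levels + 1)[1:-1]
    for j in range(X.shape[1]):
        edges = np.quantile(X[:, j], qs)
        out[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return out


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) between two small-alphabet integer arrays."""
    a = np.asarray(a)
    b = np.asarray(b)
    la = int(a.max()) + 1 if len(a) else 1
    lb = int(b.max()) + 1 if len(b) else 1
    joint = np.bincount(a * lb + b, minlength=la * lb).astype(float)
    joint = joint.reshape(la, lb) / len(a)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(pa, pb)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mrmr_select(
    X: np.ndarray, y: np.ndarray, k: int, levels: int = 3
) -> np.ndarray:
    """Greedy mRMR (difference form) feature ranking.

    Selects ``k`` features maximizing MI(feature; y) minus the mean MI with
    already-selected features.  Ties break toward the lowest feature index.
    Returns indices in selection order.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(np.int64).ravel()
    n, d = X.shape
    if k > d:
        raise ValueError(f"k={k} exceeds the {d} available features")
    Xd = discretize_quantile(X, levels=levels)
    relevance = np.array([mutual_information(Xd[:, j], y) for j in range(d)])

    selected: list[int] = []
    remaining = np.ones(d, dtype=bool)
    red_sum = np.zeros(d)  # cumulative redundancy with the selected set
    for step in range(k):
        if step == 0:
            score = relevance.copy()
        else:
            score = relevance - red_sum / step
        score[~remaining] = -np.inf
        j = int(np.argmax(score))  # argmax takes the lowest index on ties
        selected.append(j)
        remaining[j] = False
        if step < k - 1:
            for cand in np.flatnonzero(remaining):
                red_sum[cand] += mutual_information(Xd[:, cand], Xd[:, j])
    return np.array(selected, dtype=int)


def ledoit_wolf_cov(X_class: np.ndarray) -> tuple[np.ndarray, float]:
    """Shrunk covariance (1-lam) S + lam nu I with the Ledoit-Wolf lambda.

    ``X_class`` holds raw observations of one class (rows); it is centered
    here and S is the maximum-likelihood (1/n) covariance.
    """
    X_class = np.asarray(X_class, dtype=float)
    if X_class.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    Xc = X_class - X_class.mean(axis=0)
    cov, lam = ledoit_wolf(Xc, assume_centered=True)
    return cov, float(lam)


def _pooled_shrunk_cov(
    X: np.ndarray, y: np.ndarray, shrinkage: float | None
) -> tuple[np.ndarray, float]:
    """Pooled within-class covariance, shrunk with a single LW intensity.

    The data are centered per class, pooled, and a single lambda is
    estimated on the pooled centered matrix (or forced via ``shrinkage``).
    """
    Xc = X.astype(float).copy()
    for cls in (False, True):
        sel = y == cls
        Xc[sel] -= Xc[sel].mean(axis=0)
    if shrinkage is None:
        cov, lam = ledoit_wolf(Xc, assume_centered=True)
        return cov, float(lam)
    lam = float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    S = Xc.T @ Xc / Xc.shape[0]
    nu = np.trace(S) / S.shape[0]
    return (1 - lam) * S + lam * nu * np.eye(S.shape[0]), lam


def train_rlda(
    X: np.ndarray, y: np.ndarray, shrinkage: float | None = None,
    selected: np.ndarray | None = None,
) -> TrainedModel:
    """Fit the shrinkage-LDA direction w = Sigma^-1 (mu+ - mu-).

    ``y`` is boolean with True = "+".  ``shrinkage`` overrides the
    Ledoit-Wolf intensity (0 gives the plug-in LDA).  The bias uses
    empirical class priors; it does not affect AUC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool).ravel()
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("each class needs at least 2 observations")
    mu_pos = X[y].mean(axis=0)
    mu_neg = X[~y].mean(axis=0)
    cov, lam = _pooled_shrunk_cov(X, y, shrinkage)
    w = np.linalg.solve(cov, mu_pos - mu_neg)
    b = -0.5 * w @ (mu_pos + mu_neg) + np.log(n_pos / n_neg)
    if selected is None:
        selected = np.arange(X.shape[1])
    return TrainedModel(weights=w, bias=float(b), shrinkage=lam,
                        selected=np.asarray(selected, dtype=int))


def decision_values(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """w^T x + b for observations already restricted to ``model.selected``."""
    return np.asarray(X, dtype=float) @ model.weights + model.bias


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k_select: int | None = None,
    n_folds: int = 5,
    seed: int = 0,
    shrinkage: float | None = None,
    mrmr_levels: int = 3,
) -> CVResult:
    """Stratified k-fold CV with in-fold mRMR selection and shrinkage LDA.

    ``k_select=None`` (or the full feature count) disables selection.
    Held-out decision values are scored per fold with ROC AUC ("+" = True
    is the positive class) and averaged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool).ravel()
    counts = (int((~y).sum()), int(y.sum()))
    if min(counts) < n_folds:
        raise ValueError(
            f"class counts {counts} too small to stratify into {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    assign = np.empty(len(y), dtype=int)
    fold_aucs = []
    selected_per_fold = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if k_select is None or k_select >= X.shape[1]:
            sel = np.arange(X.shape[1])
        else:
            sel = mrmr_select(X[tr], y[tr], k_select, levels=mrmr_levels)
        model = train_rlda(X[tr][:, sel], y[tr], shrinkage=shrinkage,
                           selected=sel)
        scores[te] = decision_values(model, X[te][:, sel])
        assign[te] = fold
        fold_aucs.append(roc_auc(scores[te], y[te]))
        selected_per_fold.append(sel)
    fold_aucs = np.array(fold_aucs)
    return CVResult(
        fold_scores=scores,
        fold_assignment=assign,
        fold_aucs=fold_aucs,
        auc_mean=float(fold_aucs.mean()),
        selected_per_fold=selected_per_fold,
    )


def dump_selected_features(cv: CVResult, path, n_bins: int) -> None:
    """Debug CSV of in-fold mRMR picks: fold, rank, electrode, bin.

    Feature indices are decoded assuming the (electrode, bin) layout of a
    flattened epoch tensor with ``n_bins`` bins per electrode.
    """
    import csv

    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["fold", "rank", "electrode", "bin"])
        for fold, sel in enumerate(cv.selected_per_fold):
            for rank, idx in enumerate(sel):
                writer.writerow([fold, rank, int(idx) // n_bins, int(idx) % n_bins])
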