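"""Feature-selection scorers and merit tracking.

At each analysis window and training fold, every feature is scalarized to
one column (see :mod:`eegdecode.reduction`) and scored; the top ``k``
(default 5) features are combined for decoding. Seven scorers are built
in — five supervised (Fisher score, mutual information, mRMR, ReliefF,
L1-logistic "lasso") and two unsupervised (Laplacian score,
correlation-based "cfs") — and a registry accepts external scorers with
the same signature, so the pipeline stays method-agnostic.

All scorers return one value per column with higher = more informative,
and see training trials only.

A feature's *merit* at a window is the fraction of selection events
(folds x category pairs) in which it entered the chosen top-k set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .datasets import ConfigurationError

__all__ = [
    "SelectionResult",
    "SCORERS",
    "register_scorer",
    "score_features",
    "score_supervised",
    "score_unsupervised",
    "select_top_k",
    "merit_timecourse",
    "fisher_score",
]


@dataclass
class SelectionResult:
    """Scores and the chosen top-k feature ids for one selection event."""

    method: str
    window_center: float
    fold: int
    scores: np.ndarray
    chosen: list[int]
    k: int = 5
    pair: tuple | None = None


# ---------------------------------------------------------------------------
# helpers


def _equal_freq_bins(col: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Discretize a column into equal-frequency bins (deterministic)."""
    ranks = np.argsort(np.argsort(col, kind="stable"), kind="stable")
    return (ranks * n_bins) // len(col)


def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) between two discrete vectors."""
    n = len(a)
    joint = pd.crosstab(a, b).to_numpy() / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def fisher_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column Fisher criterion (mu1-mu2)^2 / (s1^2 + s2^2)."""
    classes = np.unique(y)
    m0 = X[y == classes[0]].mean(axis=0)
    m1 = X[y == classes[1]].mean(axis=0)
    v0 = X[y == classes[0]].var(axis=0, ddof=1)
    v1 = X[y == classes[1]].var(axis=0, ddof=1)
    denom = v0 + v1
    out = np.zeros(X.shape[1])
    ok = denom > 0
    out[ok] = (m1 - m0)[ok] ** 2 / denom[ok]
    return out


def _mutinf_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        if X[:, j].std() == 0:
            scores[j] = 0.0
        else:
            scores[j] = _mi_discrete(_equal_freq_bins(X[:, j]), y)
    return scores


def _mrmr_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Greedy max-relevance min-redundancy; score = selection order reversed."""
    p = X.shape[1]
    binned = [_equal_freq_bins(X[:, j]) for j in range(p)]
    relevance = np.array(
        [0.0 if X[:, j].std() == 0 else _mi_discrete(binned[j], y) for j in range(p)]
    )
    order: list[int] = []
    remaining = list(range(p))
    first = int(np.argmax(relevance))
    order.append(first)
    remaining.remove(first)
    red_cache: dict[tuple[int, int], float] = {}

    def red(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in red_cache:
            red_cache[key] = _mi_discrete(binned[a], binned[b])
        return red_cache[key]

    while remaining:
        crit = [
            relevance[j] - np.mean([red(j, c) for c in order]) for j in remaining
        ]
        pick = remaining[int(np.argmax(crit))]
        order.append(pick)
        remaining.remove(pick)
    scores = np.empty(p)
    for rank, j in enumerate(order):
        scores[j] = p - rank
    return scores


def _relief_score(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
    n_samples: int = 50, n_neighbors: int = 10,
) -> np.ndarray:
    """Binary ReliefF with sampled instances and range-normalized diffs."""
    n, p = X.shape
    rng = rng if rng is not None else np.random.default_rng(0)
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xn = X / span
    idx = rng.choice(n, size=min(n_samples, n), replace=False)
    classes = np.unique(y)
    w = np.zeros(p)
    d = cdist(Xn[idx], Xn)
    for row, i in enumerate(idx):
        for cls in classes:
            mask = y == cls
            mask_i = mask.copy()
            mask_i[i] = False
            cand = np.flatnonzero(mask_i)
            if cand.size == 0:
                continue
            near = cand[np.argsort(d[row, cand], kind="stable")[:n_neighbors]]
            diff = np.abs(Xn[near] - Xn[i]).mean(axis=0)
            if cls == y[i]:
                w -= diff
            else:
                w += diff
    return w / len(idx)


_LASSO_LAMBDAS = np.logspace(-3, 1, 7)


def _lasso_score(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """|coefficients| of an L1 logistic fit at an internally validated lambda.

    The regularization grid spans 1e-3..1e1 (7 points) with a 3-fold
    stratified internal validation on the training data; exact score ties
    (typically zeroed coefficients) are broken by the Fisher score.
    """
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / std
    y01 = (y == np.unique(y)[1]).astype(int)
    best_lam, best_acc = _LASSO_LAMBDAS[0], -1.0
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
    splits = list(skf.split(Xs, y01))
    for lam in _LASSO_LAMBDAS:
        accs = []
        for tr, te in splits:
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / lam, solver="liblinear", max_iter=200
            )
            clf.fit(Xs[tr], y01[tr])
            accs.append(clf.score(Xs[te], y01[te]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_lam = acc, lam
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / best_lam, solver="liblinear", max_iter=200
    )
    clf.fit(Xs, y01)
    coef = np.abs(clf.coef_.ravel())
    fisher = fisher_score(X, y)
    fmax = fisher.max()
    tie_break = fisher / fmax if fmax > 0 else fisher
    return coef + 1e-9 * tie_break


def _laplacian_score(X: np.ndarray, n_neighbors: int = 5) -> np.ndarray:
    """Negated Laplacian score on a kNN heat-kernel graph (higher = better)."""
    n, p = X.shape
    d2 = cdist(X, X, "sqeuclidean")
    t = d2[d2 > 0].mean() if (d2 > 0).any() else 1.0
    W = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(d2[i], kind="stable")
        nbrs = [j for j in order if j != i][:n_neighbors]
        W[i, nbrs] = np.exp(-d2[i, nbrs] / t)
    W = np.maximum(W, W.T)  # symmetrize the kNN graph
    D = W.sum(axis=1)
    L = np.diag(D) - W
    scores = np.empty(p)
    dsum = D.sum()
    for j in range(p):
        f = X[:, j]
        if f.std() == 0:
            scores[j] = -np.inf  # constant column: worst
            continue
        f_t = f - (f @ D) / dsum  # remove the trivial all-ones component
        denom = f_t @ (D * f_t)
        if denom <= 1e-12 * float(f.var()) * dsum:
            scores[j] = -np.inf
        else:
            scores[j] = -(f_t @ L @ f_t) / denom
    return scores


def _cfs_score(X: np.ndarray) -> np.ndarray:
    """1 - mean |Pearson correlation| with the other columns."""
    p = X.shape[1]
    std = X.std(axis=0)
    scores = np.empty(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    for j in range(p):
        if std[j] == 0:
            scores[j] = -1.0  # constant column: worst
            continue
        others = np.abs(np.delete(corr[j], j))
        others = others[np.isfinite(others)]
        scores[j] = 1.0 - (others.mean() if others.size else 0.0)
    return scores


# ---------------------------------------------------------------------------
# registry and public API

SCORERS: dict[str, dict] = {
    "fisher": {"supervised": True, "func": lambda X, y, rng: fisher_score(X, y)},
    "mutinffs": {"supervised": True, "func": lambda X, y, rng: _mutinf_score(X, y)},
    "mrmr": {"supervised": True, "func": lambda X, y, rng: _mrmr_score(X, y)},
    "relief": {"supervised": True, "func": _relief_score},
    "lasso": {"supervised": True, "func": _lasso_score},
    "laplacian": {"supervised": False, "func": lambda X, rng: _laplacian_score(X)},
    "cfs": {"supervised": False, "func": lambda X, rng: _cfs_score(X)},
}


def register_scorer(name: str, func, supervised: bool) -> None:
    """Register a plug-in scorer.

    Supervised scorers are called as ``func(X, y, rng)``, unsupervised as
    ``func(X, rng)``; both must return one score per column, higher =
    more informative.
    """
    SCORERS[name] = {"supervised": supervised, "func": func}


def score_supervised(
    X: np.ndarray, y: np.ndarray, method: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    X = np.asarray(X, float)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ConfigurationError("supervised scorers need exactly two classes")
    entry = SCORERS[method]
    if not entry["supervised"]:
        raise ConfigurationError(f"{method} is an unsupervised scorer")
    rng = rng if rng is not None else np.random.default_rng(0)
    return np.asarray(entry["func"](X, y, rng), float)


def score_unsupervised(
    X: np.ndarray, method: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    X = np.asarray(X, float)
    entry = SCORERS[method]
    if entry["supervised"]:
        raise ConfigurationError(f"{method} is a supervised scorer")
    rng = rng if rng is not None else np.random.default_rng(0)
    return np.asarray(entry["func"](X, rng), float)


def score_features(
    X: np.ndarray,
    y: np.ndarray | None,
    method: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Dispatch to the registered scorer, supervised or not."""
    if method not in SCORERS:
        raise ConfigurationError(
            f"unknown selection method {method!r}; valid: {sorted(SCORERS)}"
        )
    if SCORERS[method]["supervised"]:
        return score_supervised(X, y, method, rng)
    return score_unsupervised(X, method, rng)


def select_top_k(scores: np.ndarray, k: int = 5) -> list[int]:
    """Ids of the top-k scores, descending, ties broken by feature id."""
    scores = np.asarray(scores, float)
    if np.isnan(scores).any():
        raise ConfigurationError("selection scores contain NaN")
    if k > scores.size:
        raise ConfigurationError(f"k={k} exceeds number of features {scores.size}")
    order = np.lexsort((np.arange(scores.size), -scores))
    return [int(i) for i in order[:k]]


def merit_timecourse(
    results: list[SelectionResult], feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature, per-window selection frequency in [0, 1].

    Rows are window centers (ms), columns feature ids (or names); each
    entry is (#events the feature was chosen) / (#selection events at that
    window), so each row sums to k.
    """
    if not results:
        raise ConfigurationError("no selection results")
    n_feat = results[0].scores.size
    windows = sorted({r.window_center for r in results})
    counts = {wc: np.zeros(n_feat) for wc in windows}
    events = {wc: 0 for wc in windows}
    for r in results:
        events[r.window_center] += 1
        for j in r.chosen:
            counts[r.window_center][j] += 1
    merit = np.vstack([counts[wc] / events[wc] for wc in windows])
    cols = feature_names if feature_names is not None else list(range(n_feat))
    return pd.DataFrame(merit, index=windows, columns=cols)
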