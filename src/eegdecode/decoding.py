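"""Time-resolved pairwise LDA decoding with stratified cross-validation.

Each category pair is decoded independently at every analysis window with
10-fold stratified cross-validation. Within a fold, the pipeline runs the
leakage-free PCA stages (and, in combination mode, feature selection) on
training trials only, then classifies the left-out trials with a linear
discriminant whose pooled within-class covariance is shrunk toward the
scaled identity (gamma = 0.05) so it stays invertible when the electrode
count approaches the per-fold trial count. Accuracies are pooled over all
test trials across folds and averaged over category pairs per participant;
chance is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .datasets import ConfigurationError, EpochedDataset
from .features import ALL_FEATURES, FeatureMatrix, extract_feature_tensor
from .reduction import combine_selected, equalize_multivalued, scalarize_for_selection
from .selection import SelectionResult, score_features, select_top_k, SCORERS
from .windows import WindowSpec

__all__ = [
    "FoldPlan",
    "DecodingCurve",
    "make_folds",
    "lda_fit_predict",
    "decode_pair",
    "run_study",
    "CHANCE",
]

CHANCE = 0.5
LDA_SHRINKAGE = 0.05


@dataclass
class FoldPlan:
    """Stratified assignment of trials to test folds."""

    n_folds: int
    fold_ids: np.ndarray  # test-fold id per trial

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_ids == fold


@dataclass
class DecodingCurve:
    """Participant x window accuracies for one decoding method."""

    method: str
    accuracy: np.ndarray  # (n_participants, n_windows)
    window_centers: np.ndarray  # ms
    chance: float = CHANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accuracy = np.atleast_2d(np.asarray(self.accuracy, float))
        self.window_centers = np.asarray(self.window_centers, float)
        if self.accuracy.shape[1] != self.window_centers.size:
            raise ConfigurationError("accuracy columns must match window count")
        if self.accuracy.min() < 0 or self.accuracy.max() > 1:
            raise ConfigurationError("accuracies must lie in [0, 1]")


def make_folds(labels: np.ndarray, n_folds: int, seed: int) -> FoldPlan:
    """Stratified, seeded, deterministic fold plan.

    Each class's trials are shuffled and dealt round-robin across folds,
    so per-fold class proportions are within one trial of the global mix
    and every training set contains both classes.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold_ids = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_folds:
            raise ConfigurationError(
                f"class {cls} has {idx.size} trials < n_folds={n_folds}"
            )
        idx = rng.permutation(idx)
        fold_ids[idx] = np.arange(idx.size) % n_folds
    return FoldPlan(n_folds=n_folds, fold_ids=fold_ids)


def lda_fit_predict(
    train: np.ndarray,
    y_train: np.ndarray,
    test: np.ndarray,
    shrinkage: float = LDA_SHRINKAGE,
) -> np.ndarray:
    """Two-class LDA with covariance shrinkage toward the scaled identity.

    The pooled within-class covariance S (class covariances weighted by
    class priors) is replaced by (1-gamma) S + gamma (tr S / p) I, which
    is always invertible for gamma > 0. Deterministic; priors come from
    training class frequencies.
    """
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size != 2:
        raise ConfigurationError("lda_fit_predict needs exactly two classes")
    n, p = train.shape
    mus, covs, priors = [], [], []
    for cls in classes:
        Xc = train[y_train == cls]
        mu = Xc.mean(axis=0)
        Z = Xc - mu
        mus.append(mu)
        covs.append(Z.T @ Z / Xc.shape[0])
        priors.append(Xc.shape[0] / n)
    S = priors[0] * covs[0] + priors[1] * covs[1]
    S = (1.0 - shrinkage) * S + shrinkage * (np.trace(S) / p) * np.eye(p)
    coef = np.linalg.solve(S, mus[1] - mus[0])
    intercept = -0.5 * (mus[0] + mus[1]) @ coef + np.log(priors[1] / priors[0])
    scores = test @ coef + intercept
    return np.where(scores > 0, classes[1], classes[0])


def _decode_windows_individual(
    tensor: list[FeatureMatrix], labels: np.ndarray, folds: FoldPlan
) -> np.ndarray:
    """Pooled test accuracy per window for one feature (no selection)."""
    accs = np.empty(len(tensor))
    for wi, fm in enumerate(tensor):
        X = fm.values
        preds = np.empty(labels.size, dtype=labels.dtype)
        for f in range(folds.n_folds):
            te = folds.test_mask(f)
            tr = ~te
            Xe = equalize_multivalued(X, fm.n_electrodes, tr)
            preds[te] = lda_fit_predict(Xe[tr], labels[tr], Xe[te])
        accs[wi] = np.mean(preds == labels)
    return accs


def _decode_windows_combined(
    tensors: dict[str, list[FeatureMatrix]],
    labels: np.ndarray,
    folds: FoldPlan,
    method: str,
    k: int,
    rng: np.random.Generator,
    pair: tuple | None = None,
) -> tuple[np.ndarray, list[SelectionResult]]:
    """Selection-based feature combination decoding, per window."""
    names = list(tensors)
    n_windows = len(tensors[names[0]])
    e = tensors[names[0]][0].n_electrodes
    accs = np.empty(n_windows)
    records: list[SelectionResult] = []
    for wi in range(n_windows):
        center = tensors[names[0]][wi].window_center
        preds = np.empty(labels.size, dtype=labels.dtype)
        for f in range(folds.n_folds):
            te = folds.test_mask(f)
            tr = ~te
            eq = {
                name: equalize_multivalued(tensors[name][wi].values, e, tr)
                for name in names
            }
            scalar = np.column_stack(
                [scalarize_for_selection(eq[name], tr)[:, 0] for name in names]
            )
            scores = score_features(scalar[tr], labels[tr], method, rng)
            chosen = select_top_k(scores, k)
            records.append(
                SelectionResult(
                    method=method,
                    window_center=center,
                    fold=f,
                    scores=scores,
                    chosen=chosen,
                    k=k,
                    pair=pair,
                )
            )
            combined = combine_selected([eq[names[j]] for j in chosen], e, tr)
            preds[te] = lda_fit_predict(combined[tr], labels[tr], combined[te])
        accs[wi] = np.mean(preds == labels)
    return accs, records


def decode_pair(
    tensors: dict[str, list[FeatureMatrix]] | list[FeatureMatrix],
    labels: np.ndarray,
    pair: tuple,
    folds: FoldPlan,
    method: str | None = None,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[SelectionResult]]:
    """Decode one category pair at every window.

    ``tensors`` and ``labels`` must already be restricted to the pair's
    trials. Pass a single feature's tensor for individual-feature decoding
    or a dict of tensors plus a selection ``method`` for combination mode.
    Returns (accuracy per window, selection records).
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    if sorted(pair) != sorted(present.tolist()):
        raise ConfigurationError(f"labels do not match pair {pair}")
    if isinstance(tensors, dict):
        if method is None:
            raise ConfigurationError("combination mode needs a selection method")
        rng = rng if rng is not None else np.random.default_rng(0)
        return _decode_windows_combined(tensors, labels, folds, method, k, rng,
                                        pair=pair)
    return _decode_windows_individual(tensors, labels, folds), []


def _required_features(methods: list[str], feature_pool: tuple[str, ...]) -> list[str]:
    needed: list[str] = []
    for m in methods:
        if m.startswith("fs:"):
            for name in feature_pool:
                if name not in needed:
                    needed.append(name)
        elif m not in needed:
            needed.append(m)
    return needed


def run_study(
    cohort: list[EpochedDataset],
    methods: list[str],
    spec: WindowSpec,
    seed: int,
    n_folds: int = 10,
    k_selected: int = 5,
    feature_pool: tuple[str, ...] = ALL_FEATURES,
) -> tuple[dict[str, DecodingCurve], dict[str, list[SelectionResult]]]:
    """Decode every method for every participant, averaged over pairs.

    ``methods`` entries are feature names (individual-feature decoding) or
    ``"fs:<scorer>"`` (selection-based combination over ``feature_pool``).
    All C(n_categories, 2) pairs are decoded per participant with a shared
    fold plan per pair, and accuracies averaged over pairs. Returns the
    curve per method plus the selection records per combination method.
    """
    if not cohort:
        raise ConfigurationError("empty cohort")
    for m in methods:
        if m.startswith("fs:"):
            if m[3:] not in SCORERS:
                raise ConfigurationError(f"unknown selection method {m[3:]!r}")
        elif m not in ALL_FEATURES:
            raise ConfigurationError(f"unknown feature {m!r}")
    needed = _required_features(methods, feature_pool)
    curves_acc: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    selections: dict[str, list[SelectionResult]] = {
        m: [] for m in methods if m.startswith("fs:")
    }
    window_centers: np.ndarray | None = None
    for p_idx, ds in enumerate(cohort):
        tensors = {
            name: extract_feature_tensor(ds, spec, name) for name in needed
        }
        if window_centers is None:
            first = tensors[needed[0]]
            window_centers = np.array([fm.window_center for fm in first])
        cats = np.unique(ds.labels)
        pairs = list(combinations(cats.tolist(), 2))
        pair_accs: dict[str, list[np.ndarray]] = {m: [] for m in methods}
        for pr_idx, pair in enumerate(pairs):
            mask = np.isin(ds.labels, pair)
            labels_sub = ds.labels[mask]
            fold_seed = int(
                np.random.SeedSequence([seed, 31, p_idx, pr_idx]).generate_state(1)[0]
                % (2**31)
            )
            folds = make_folds(labels_sub, n_folds, fold_seed)
            sub = {
                name: [
                    FeatureMatrix(
                        fm.feature_name,
                        fm.window_center,
                        fm.values[mask],
                        fm.f,
                        fm.n_electrodes,
                    )
                    for fm in tensors[name]
                ]
                for name in needed
            }
            for m in methods:
                if m.startswith("fs:"):
                    rng = np.random.default_rng(
                        np.random.SeedSequence([seed, 47, p_idx, pr_idx])
                    )
                    accs, recs = decode_pair(
                        {name: sub[name] for name in feature_pool},
                        labels_sub,
                        pair,
                        folds,
                        method=m[3:],
                        k=k_selected,
                        rng=rng,
                    )
                    selections[m].extend(recs)
                else:
                    accs, _ = decode_pair(sub[m], labels_sub, pair, folds)
                pair_accs[m].append(accs)
        for m in methods:
            curves_acc[m].append(np.mean(pair_accs[m], axis=0))
    curves = {
        m: DecodingCurve(
            method=m,
            accuracy=np.vstack(curves_acc[m]),
            window_centers=window_centers,
            meta={"n_pairs": len(pairs), "seed": seed, "n_folds": n_folds},
        )
        for m in methods
    }
    return curves, selections
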