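"""Fold plans, shrinkage LDA and the time-resolved decoding pipeline."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from eegdecode import WindowSpec, run_study
from eegdecode.datasets import ConfigurationError
from eegdecode.decoding import decode_pair, lda_fit_predict, make_folds
from eegdecode.features import extract_feature_tensor
from eegdecode.synth import SyntheticConfig, generate_cohort, generate_participant


def test_fold_plan_sizes_and_stratification():
    labels = np.repeat([0, 1], 50)
    plan = make_folds(labels, 10, seed=0)
    for f in range(10):
        te = plan.test_mask(f)
        assert te.sum() == 10
        assert (~te).sum() == 90  # trains on 90% of trials
        # class proportions within one trial of the global 50/50 mix
        assert abs(labels[te].sum() - 5) <= 1
        assert len(np.unique(labels[~te])) == 2
    assert np.bincount(plan.fold_ids).sum() == 100


def test_fold_plan_deterministic_and_seed_sensitive():
    labels = np.repeat([0, 1], 30)
    a = make_folds(labels, 10, seed=4)
    b = make_folds(labels, 10, seed=4)
    c = make_folds(labels, 10, seed=5)
    np.testing.assert_array_equal(a.fold_ids, b.fold_ids)
    assert not np.array_equal(a.fold_ids, c.fold_ids)


def test_fold_plan_rejects_small_classes():
    with pytest.raises(ConfigurationError, match="n_folds"):
        make_folds(np.repeat([0, 1], 5), 10, seed=0)


def test_lda_separable_and_null_accuracy(rng):
    mu = np.zeros(6)
    X0 = rng.standard_normal((100, 6)) + mu
    X1 = rng.standard_normal((100, 6)) + 10.0  # 10 sigma separation
    Xtr = np.vstack([X0[:80], X1[:80]])
    ytr = np.repeat([0, 1], 80)
    Xte = np.vstack([X0[80:], X1[80:]])
    yte = np.repeat([0, 1], 20)
    acc = np.mean(lda_fit_predict(Xtr, ytr, Xte) == yte)
    assert acc >= 0.99
    # identical class distributions: accuracy in the chance band
    Xn = rng.standard_normal((160, 6))
    yn = np.repeat([0, 1], 80)
    Xn_te = rng.standard_normal((100, 6))
    yn_te = np.repeat([0, 1], 50)
    acc_null = np.mean(lda_fit_predict(Xn, yn, Xn_te) == yn_te)
    assert 0.35 <= acc_null <= 0.65


def test_lda_label_flip_symmetry(rng):
    X = rng.standard_normal((40, 5))
    y = np.repeat([0, 1], 20)
    Xt = rng.standard_normal((15, 5))
    a = lda_fit_predict(X, y, Xt)
    b = lda_fit_predict(X, 1 - y, Xt)
    np.testing.assert_array_equal(a, 1 - b)


def test_lda_matches_sklearn_shrinkage(rng):
    for _ in range(5):
        X = rng.standard_normal((60, 8))
        y = (rng.random(60) > 0.4).astype(int)
        Xt = rng.standard_normal((25, 8))
        mine = lda_fit_predict(X, y, Xt)
        ref = (
            LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.05)
            .fit(X, y)
            .predict(Xt)
        )
        np.testing.assert_array_equal(mine, ref)


def _pair_setup(code, effect_size, seed=3):
    cfg = SyntheticConfig(
        n_participants=1, n_categories=2, trials_per_category=24,
        n_electrodes=8, code=code, effect_size=effect_size, seed=seed,
    )
    ds = generate_participant(cfg, 0)
    spec = WindowSpec(50.0, 20.0)
    tensor = extract_feature_tensor(ds, spec, "mean")
    folds = make_folds(ds.labels, 10, seed=1)
    centers = np.array([fm.window_center for fm in tensor])
    return ds, tensor, folds, centers


def test_decode_pair_finds_injected_mean_code():
    ds, tensor, folds, centers = _pair_setup("mean", 1.5)
    accs, _ = decode_pair(tensor, ds.labels, (0, 1), folds)
    band = (centers > 50) & (centers < 350)
    pre = centers < 0
    assert accs[band].mean() > 0.6
    assert 0.35 < accs[pre].mean() < 0.65  # no pre-stimulus code injected


def test_decode_pair_null_data_at_chance():
    ds, tensor, folds, centers = _pair_setup("none", 0.0)
    accs, _ = decode_pair(tensor, ds.labels, (0, 1), folds)
    assert 0.40 < accs.mean() < 0.60


def test_run_study_pair_combinatorics_and_determinism():
    spec = WindowSpec(50.0, 200.0)  # coarse grid: combinatorics only
    for n_cat, n_pairs in [(4, 6), (6, 15)]:
        cfg = SyntheticConfig(
            n_participants=1, n_categories=n_cat, trials_per_category=10,
            n_electrodes=4, code="none", seed=2,
        )
        with pytest.warns(UserWarning):
            cohort = generate_cohort(cfg)
        curves, _ = run_study(cohort, ["mean"], spec, seed=0, n_folds=5)
        assert curves["mean"].meta["n_pairs"] == n_pairs
    curves2, _ = run_study(cohort, ["mean"], spec, seed=0, n_folds=5)
    np.testing.assert_array_equal(
        curves["mean"].accuracy, curves2["mean"].accuracy
    )


def test_run_study_combined_mode_records_selections():
    cfg = SyntheticConfig(
        n_participants=1, n_categories=2, trials_per_category=20,
        n_electrodes=4, code="mean", effect_size=2.0, seed=6,
    )
    cohort = generate_cohort(cfg)
    pool = ("mean", "variance", "median", "kurtosis", "skewness", "signal_power")
    spec = WindowSpec(50.0, 100.0)
    curves, selections = run_study(
        cohort, ["fs:fisher"], spec, seed=1, n_folds=5, feature_pool=pool
    )
    recs = selections["fs:fisher"]
    n_windows = curves["fs:fisher"].window_centers.size
    assert len(recs) == n_windows * 5  # one event per window per fold
    assert all(len(r.chosen) == 5 and len(set(r.chosen)) == 5 for r in recs)
    # the informative feature is almost always selected in the coded band
    centers = curves["fs:fisher"].window_centers
    band = set(centers[(centers > 50) & (centers < 350)])
    in_band = [r for r in recs if r.window_center in band]
    hit = np.mean([0 in r.chosen for r in in_band])
    assert hit >= 0.8


def test_selection_ignores_test_fold_labels():
    """Permuting test-fold labels must not change what gets selected."""
    cfg = SyntheticConfig(
        n_participants=1, n_categories=2, trials_per_category=20,
        n_electrodes=4, code="mean", effect_size=1.5, seed=8,
    )
    ds = generate_participant(cfg, 0)
    spec = WindowSpec(50.0, 200.0)
    pool = ("mean", "variance", "median")
    tensors = {n: extract_feature_tensor(ds, spec, n) for n in pool}
    folds = make_folds(ds.labels, 5, seed=0)
    te = folds.test_mask(0)
    labels_perm = ds.labels.copy()
    labels_perm[te] = np.random.default_rng(0).permutation(labels_perm[te])
    if not np.array_equal(sorted(np.unique(labels_perm[te])), [0, 1]):
        labels_perm = ds.labels  # permutation degenerate; keep original
    _, recs_a = decode_pair(tensors, ds.labels, (0, 1), folds, method="fisher",
                            k=2, rng=np.random.default_rng(5))
    _, recs_b = decode_pair(tensors, labels_perm, (0, 1), folds, method="fisher",
                            k=2, rng=np.random.default_rng(5))
    for ra, rb in zip(recs_a, recs_b):
        if ra.fold == 0:  # training rows identical for fold 0
            assert ra.chosen == rb.chosen


def test_unknown_methods_rejected():
    cfg = SyntheticConfig(n_participants=1, n_categories=2,
                          trials_per_category=20, n_electrodes=4, seed=0)
    cohort = generate_cohort(cfg)
    spec = WindowSpec(50.0, 200.0)
    with pytest.raises(ConfigurationError, match="unknown feature"):
        run_study(cohort, ["nope"], spec, seed=0)
    with pytest.raises(ConfigurationError, match="unknown selection"):
        run_study(cohort, ["fs:nope"], spec, seed=0)
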