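"""Feature extractors against naive oracles, closed forms and simulations."""

import numpy as np
import pytest

import oracles
from eegdecode import EpochedDataset, WindowSpec
from eegdecode.datasets import ConfigurationError
from eegdecode.features import (
    ALL_FEATURES,
    autocorrelation,
    cross_correlation_profile,
    default_ac_lag,
    entropies,
    extract_feature_tensor,
    feature_dim,
    fractal_dimensions,
    hilbert_features,
    hjorth,
    hurst_exponent,
    lz_complexity,
    moments_and_median,
    raw_samples,
    spectral_summary,
    wavelet_features,
)
from eegdecode.windows import sliding_windows, window_centers


def _random_windows(n, w, seed=0):
    return np.random.default_rng(seed).standard_normal((n, w))


# ---------------------------------------------------------------------------
# sliding windows


def _dataset(fs, n_trials=3, e=2, span=(-200.0, 1000.0), seed=0):
    n = int(round((span[1] - span[0]) * fs / 1000.0))
    rng = np.random.default_rng(seed)
    return EpochedDataset(
        data=rng.standard_normal((n_trials, e, n)),
        labels=np.arange(n_trials) % 2,
        fs=fs,
        t_first_sample=span[0],
    )


def test_window_centers_follow_full_window_inside_rule():
    ds = _dataset(fs=1000.0)
    idx, times, w = window_centers(ds, WindowSpec(50.0, 5.0))
    assert w == 50
    assert times[0] == -175.0
    assert times[-1] == 975.0
    # enumerate by the stated rule as an independent check
    half = w // 2
    valid = [c for c in range(ds.n_samples) if c - half >= 0 and c - half + w - 1 <= ds.n_samples - 1]
    expected = [ds.t_first_sample + c for c in valid[::5]]
    assert np.allclose(times, expected)


def test_window_sample_count_rounds_half_up():
    assert WindowSpec(50.0, 5.0).n_samples(250.0) == 13
    assert WindowSpec(50.0, 5.0).n_samples(1000.0) == 50


def test_window_slices_have_w_samples_and_are_ordered():
    ds = _dataset(fs=250.0)
    out = list(sliding_windows(ds, WindowSpec(50.0, 20.0)))
    assert all(b.shape == (3, 2, 13) for _, b in out)
    centers = [c for c, _ in out]
    assert centers == sorted(centers)


def test_window_larger_than_epoch_rejected():
    ds = _dataset(fs=250.0, span=(-20.0, 30.0))
    with pytest.raises(ConfigurationError):
        list(sliding_windows(ds, WindowSpec(200.0, 5.0)))


# ---------------------------------------------------------------------------
# oracle equivalence, all 26 features


def _feature_value(name, window, fs):
    if name in ("mean", "variance", "skewness", "kurtosis", "median"):
        return moments_and_median(window)[name]
    if name == "lempel_ziv":
        return float(lz_complexity(window))
    if name in ("higuchi_fd", "katz_fd"):
        return fractal_dimensions(window)["higuchi" if name == "higuchi_fd" else "katz"]
    if name == "hurst":
        return hurst_exponent(window)
    if name in ("sample_entropy", "approx_entropy"):
        key = "sample_entropy" if name == "sample_entropy" else "approximate_entropy"
        return entropies(window)[key]
    if name == "autocorrelation":
        return autocorrelation(window, default_ac_lag(fs))
    if name in ("hjorth_mobility", "hjorth_complexity"):
        return hjorth(window)["mobility" if name == "hjorth_mobility" else "complexity"]
    return spectral_summary(window, fs)[name]


def _oracle_value(name, window, fs):
    if name in ("mean", "variance", "skewness", "kurtosis", "median"):
        return oracles.naive_moments(window)[name]
    if name == "lempel_ziv":
        return float(oracles.naive_lz76(window))
    if name == "higuchi_fd":
        return oracles.naive_higuchi(window)
    if name == "katz_fd":
        return oracles.naive_katz(window)
    if name == "hurst":
        return oracles.naive_hurst(window)
    if name in ("sample_entropy", "approx_entropy"):
        key = "sample_entropy" if name == "sample_entropy" else "approximate_entropy"
        return oracles.naive_entropies(window)[key]
    if name == "autocorrelation":
        return oracles.naive_autocorr(window, default_ac_lag(fs))
    if name == "hjorth_mobility":
        return oracles.naive_hjorth(window)["mobility"]
    if name == "hjorth_complexity":
        return oracles.naive_hjorth(window)["complexity"]
    return oracles.naive_spectral(window, fs)[name]


@pytest.mark.parametrize("name", [f for f in ALL_FEATURES if f not in
                                  ("cross_correlation", "wavelet",
                                   "hilbert_amplitude", "hilbert_phase", "samples")])
def test_single_valued_matches_naive_oracle(name):
    fs = 1000.0
    n_windows = 30 if name in ("sample_entropy", "approx_entropy") else 100
    for i, win in enumerate(_random_windows(n_windows, 50, seed=hash(name) % 2**31)):
        got = _feature_value(name, win, fs)
        want = _oracle_value(name, win, fs)
        assert got == pytest.approx(want, abs=1e-9), f"window {i}"


def test_multivalued_match_naive_oracles(rng):
    for win in _random_windows(100, 50, seed=42):
        np.testing.assert_allclose(
            wavelet_features(win), oracles.naive_wavelet(win), atol=1e-9
        )
        np.testing.assert_allclose(
            wavelet_features(win, include_approximation=True),
            oracles.naive_wavelet(win, include_approximation=True),
            atol=1e-9,
        )
        hf = hilbert_features(win)
        nf = oracles.naive_hilbert(win)
        np.testing.assert_allclose(hf["amplitude"], nf["amplitude"], atol=1e-9)
        np.testing.assert_allclose(hf["phase"], nf["phase"], atol=1e-9)
        np.testing.assert_array_equal(raw_samples(win), win)
    block = rng.standard_normal((5, 50))
    for el in range(5):
        np.testing.assert_allclose(
            cross_correlation_profile(block, el),
            oracles.naive_cross_correlation(block, el),
            atol=1e-9,
        )


# ---------------------------------------------------------------------------
# hand-computed and closed-form examples


def test_moment_hand_values():
    m = moments_and_median(np.array([1.0, 2.0, 3.0, 4.0]))
    assert m["mean"] == 2.5
    assert m["median"] == 2.5
    assert m["variance"] == pytest.approx(5.0 / 3.0)
    sym = moments_and_median(np.array([-2.0, -1.0, 1.0, 2.0]))
    assert sym["skewness"] == pytest.approx(0.0, abs=1e-12)


def test_lz_hand_enumeration():
    assert lz_complexity(np.ones(10)) == 2  # "111..." -> 1|11111...
    assert lz_complexity(np.arange(1, 7)) == 3  # 000111 -> 0|001|11
    win = _random_windows(1, 50)[0]
    assert lz_complexity(win) == lz_complexity(3.0 * win + 11.0)  # scale-free


def test_katz_straight_line_is_one():
    assert fractal_dimensions(np.linspace(0, 5, 30))["katz"] == pytest.approx(1.0)


def test_higuchi_simulation_oracle():
    wins = _random_windows(1000, 50, seed=3)
    vals = [fractal_dimensions(w)["higuchi"] for w in wins]
    assert np.mean(vals) == pytest.approx(2.0, abs=0.15)  # white noise
    line = fractal_dimensions(np.linspace(0, 1, 50))["higuchi"]
    assert line == pytest.approx(1.0, abs=0.05)


def test_hurst_simulation_oracle():
    wins = _random_windows(1000, 64, seed=4)
    white = [hurst_exponent(w) for w in wins]
    assert np.mean(white) == pytest.approx(0.5, abs=0.1)
    walks = [hurst_exponent(np.cumsum(w)) for w in wins[:200]]
    assert np.mean(walks) > 0.7
    assert all(0.0 <= h <= 1.0 for h in white + walks)


def test_sample_entropy_simulation_oracle():
    wins = _random_windows(1000, 100, seed=5)
    vals = [entropies(w)["sample_entropy"] for w in wins]
    assert np.mean(vals) == pytest.approx(2.2, abs=0.3)  # white noise, m=2, r=0.2s
    saw = np.tile([0.0, 1.0, 2.0, 1.0], 25)
    assert entropies(saw)["sample_entropy"] < np.mean(vals)


def test_constant_window_entropies_zero():
    r = entropies(np.ones(30))
    assert r["sample_entropy"] == 0.0
    assert abs(r["approximate_entropy"]) < 1e-12
    assert r["degenerate"]


def test_autocorrelation_sine_phase_relations():
    fs = 1000.0
    t = np.arange(100) / fs
    period = 20  # samples
    x = np.sin(2 * np.pi * 50.0 * t)
    assert autocorrelation(x, period) == pytest.approx(1.0, abs=0.05)
    assert autocorrelation(x, period // 2) == pytest.approx(-1.0, abs=0.05)
    noise = _random_windows(200, 50, seed=6)
    vals = [autocorrelation(w, 10) for w in noise]
    assert np.mean(vals) == pytest.approx(0.0, abs=0.05)
    assert all(abs(v) < 0.6 for v in vals)


def test_hjorth_closed_form_for_sinusoid():
    fs, f = 250.0, 20.0
    t = np.arange(250) / fs
    x = np.sin(2 * np.pi * f * t)
    h = hjorth(x)
    assert h["mobility"] == pytest.approx(2 * np.sin(np.pi * f / fs), rel=0.01)
    assert h["complexity"] == pytest.approx(1.0, rel=0.01)
    noise = np.random.default_rng(0).standard_normal(250)
    slow = np.sin(2 * np.pi * 5.0 * t) * noise.std() * np.sqrt(2)
    assert hjorth(noise)["mobility"] > hjorth(slow)["mobility"]


def test_spectral_pure_tone_on_bin():
    fs, w = 1000.0, 50
    t = np.arange(w) / fs
    x = np.sin(2 * np.pi * 20.0 * t)  # exactly one cycle: on-bin
    s = spectral_summary(x, fs)
    assert s["mean_frequency"] == pytest.approx(20.0, abs=1e-6)
    assert s["median_frequency"] == 20.0
    assert s["sef95"] == 20.0
    assert s["signal_power"] == pytest.approx(0.5, abs=1e-6)
    # one full cycle starting at 0+: sign changes at the half and full period
    assert s["zero_crossings"] == oracles.naive_spectral(x, fs)["zero_crossings"]


def test_wavelet_counts_and_ramp():
    win = _random_windows(1, 50)[0]
    assert wavelet_features(win).size == 57
    assert wavelet_features(win, include_approximation=True).size == 61
    assert feature_dim("wavelet", 31, 50) == 57
    assert np.all(wavelet_features(np.zeros(50)) == 0.0)
    # sym2 has two vanishing moments: a linear ramp's interior D1 vanishes
    d1 = wavelet_features(np.arange(50.0))[:26]
    assert np.abs(d1[2:-2]).max() < 1e-9


def test_wavelet_short_window_reduces_levels_with_warning():
    with pytest.warns(UserWarning, match="reduced"):
        out = wavelet_features(np.random.default_rng(0).standard_normal(13))
    assert out.size > 0


def test_hilbert_sinusoid_identities():
    fs, f, w = 1000.0, 40.0, 200
    t = np.arange(w) / fs
    x = np.sin(2 * np.pi * f * t)
    hf = hilbert_features(x)
    interior = slice(w // 10, -w // 10)
    assert np.allclose(hf["amplitude"][interior], 1.0, atol=0.05)
    dphase = np.diff(np.unwrap(hf["phase"]))[interior]
    assert np.allclose(dphase, 2 * np.pi * f / fs, atol=0.02)
    assert (hf["amplitude"] >= 0).all()


def test_cross_correlation_duplicate_and_flip():
    base = _random_windows(1, 50)[0]
    block = np.vstack([base, base, -base])
    prof = cross_correlation_profile(block, 0)
    assert prof[0] == pytest.approx(1.0)
    assert prof[1] == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# tensor extraction contracts


def test_extract_shapes_and_window_count(window_spec):
    ds = _dataset(fs=250.0, n_trials=8, e=3)
    for name, f in [("mean", 1), ("samples", 13), ("cross_correlation", 2)]:
        tensor = extract_feature_tensor(ds, window_spec, name)
        assert len(tensor) == len(list(sliding_windows(ds, window_spec)))
        assert all(fm.values.shape == (8, 3 * f) for fm in tensor)
        assert all(np.isfinite(fm.values).all() for fm in tensor)


def test_extract_unknown_feature_rejected(window_spec):
    ds = _dataset(fs=250.0)
    with pytest.raises(ConfigurationError, match="unknown feature"):
        extract_feature_tensor(ds, window_spec, "not-a-feature")


def test_extractors_trial_permutation_equivariant(window_spec):
    ds = _dataset(fs=250.0, n_trials=6, e=2, seed=9)
    perm = np.array([3, 1, 5, 0, 2, 4])
    ds_p = ds.replace(data=ds.data[perm], labels=ds.labels[perm])
    for name in ("variance", "wavelet", "lempel_ziv"):
        a = extract_feature_tensor(ds, window_spec, name)
        b = extract_feature_tensor(ds_p, window_spec, name)
        for fa, fb in zip(a, b):
            np.testing.assert_allclose(fa.values[perm], fb.values, atol=1e-12)


SCALE_INVARIANT = (
    "lempel_ziv", "higuchi_fd", "katz_fd", "hurst", "sample_entropy",
    "approx_entropy", "autocorrelation", "hjorth_mobility", "hjorth_complexity",
    "zero_crossings", "mean_frequency", "median_frequency", "sef95",
)


@pytest.mark.parametrize("name", SCALE_INVARIANT)
def test_scale_invariant_features(name):
    fs = 1000.0
    for win in _random_windows(20, 50, seed=8):
        a = _feature_value(name, win, fs)
        b = _feature_value(name, 7.3 * win, fs)
        assert a == pytest.approx(b, abs=1e-8)


def test_amplitude_scaling_features_scale_accordingly():
    win = _random_windows(1, 50)[0]
    c = 3.0
    assert moments_and_median(c * win)["mean"] == pytest.approx(
        c * moments_and_median(win)["mean"]
    )
    assert moments_and_median(c * win)["variance"] == pytest.approx(
        c**2 * moments_and_median(win)["variance"]
    )
    assert spectral_summary(c * win, 1000.0)["signal_power"] == pytest.approx(
        c**2 * spectral_summary(win, 1000.0)["signal_power"]
    )
    np.testing.assert_allclose(
        wavelet_features(c * win), c * wavelet_features(win), atol=1e-9
    )
    np.testing.assert_allclose(
        hilbert_features(c * win)["amplitude"],
        c * hilbert_features(win)["amplitude"],
        atol=1e-9,
    )


def test_degenerate_windows_flagged_not_nan(window_spec):
    # fs high enough that every feature's minimum window length is met
    ds = _dataset(fs=500.0, n_trials=4, e=2)
    ds.data[0, 0, :] = 5.0  # constant trace
    for name in ("skewness", "hurst", "sample_entropy", "median_frequency"):
        tensor = extract_feature_tensor(ds, window_spec, name, baseline=False)
        assert all(np.isfinite(fm.values).all() for fm in tensor)
        assert any(fm.meta["n_degenerate"] > 0 for fm in tensor)
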