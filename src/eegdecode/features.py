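"""Window-level time-series features of epoched EEG.

26 features are computed per trial, electrode and sliding analysis window.
Twenty-one are single-valued (one number per electrode per window): the
first four moments and the median, Lempel-Ziv complexity, Higuchi and Katz
fractal dimensions, the Hurst exponent, sample and approximate entropy,
autocorrelation, Hjorth mobility and complexity, and seven spectral
summaries (mean/median frequency, zero-crossing rate, 95% spectral edge,
signal power, and power/phase at the median frequency). Five are
multi-valued: inter-electrode cross-correlation (e-1 values), discrete
wavelet detail coefficients (Symlet-2, 57 values for a 50-sample window),
Hilbert amplitude and phase envelopes (w values each) and the raw signal
samples (w values).

Scalar reference implementations operate on a single 1-D window; the
tensor extractor dispatches to vectorized equivalents where the operation
allows it. Degenerate windows (zero variance and similar) never produce
NaN: each op substitutes a documented sentinel and flags the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sp_signal

from .datasets import ConfigurationError, EpochedDataset, baseline_correct
from .windows import WindowSpec, round_half_up, sliding_windows

__all__ = [
    "ALL_FEATURES",
    "SINGLE_VALUED",
    "MULTI_VALUED",
    "FeatureMatrix",
    "extract_feature_tensor",
    "moments_and_median",
    "lz_complexity",
    "fractal_dimensions",
    "hurst_exponent",
    "entropies",
    "autocorrelation",
    "hjorth",
    "spectral_summary",
    "cross_correlation_profile",
    "wavelet_features",
    "hilbert_features",
    "raw_samples",
    "feature_dim",
]

SINGLE_VALUED = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "lempel_ziv",
    "higuchi_fd",
    "katz_fd",
    "hurst",
    "sample_entropy",
    "approx_entropy",
    "autocorrelation",
    "hjorth_mobility",
    "hjorth_complexity",
    "mean_frequency",
    "median_frequency",
    "zero_crossings",
    "sef95",
    "signal_power",
    "power_at_median_freq",
    "phase_at_median_freq",
)
MULTI_VALUED = (
    "cross_correlation",
    "wavelet",
    "hilbert_amplitude",
    "hilbert_phase",
    "samples",
)
ALL_FEATURES = SINGLE_VALUED + MULTI_VALUED

WAVELET_BASIS = "sym2"
WAVELET_LEVELS = 5


@dataclass
class FeatureMatrix:
    """One feature at one analysis window: trials x (electrodes x f).

    Columns are electrode-major, feature-element-minor. ``f`` is the number
    of values per electrode per trial (1 for single-valued features).
    """

    feature_name: str
    window_center: float
    values: np.ndarray
    f: int
    n_electrodes: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ConfigurationError("FeatureMatrix values must be 2-D")
        if self.values.shape[1] != self.n_electrodes * self.f:
            raise ConfigurationError(
                f"column count {self.values.shape[1]} != e*f = "
                f"{self.n_electrodes * self.f}"
            )
        if not np.isfinite(self.values).all():
            raise ConfigurationError("FeatureMatrix values must be finite")


# ---------------------------------------------------------------------------
# scalar per-window reference operations


def moments_and_median(window: np.ndarray) -> dict:
    """First four moments plus median of one window.

    Variance uses the n-1 denominator; skewness/kurtosis are standardized
    central moments (kurtosis raw, not excess). Zero-variance windows get
    skewness = kurtosis = 0 with the degenerate flag set.
    """
    x = np.asarray(window, float)
    if x.size < 4:
        raise ConfigurationError("moments need at least 4 samples")
    var = float(x.var(ddof=1))
    out = {
        "mean": float(x.mean()),
        "variance": var,
        "median": float(np.median(x)),
        "degenerate": var == 0.0,
    }
    if var == 0.0:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        xc = x - x.mean()
        s = np.sqrt(x.var(ddof=0))
        out["skewness"] = float(np.mean(xc**3) / s**3)
        out["kurtosis"] = float(np.mean(xc**4) / s**4)
    return out


def lz_complexity(window: np.ndarray) -> int:
    """Lempel-Ziv (LZ76) phrase count of the median-binarized window.

    Samples at or above the window median map to 1 (constant windows thus
    binarize to all ones). The count is the number of phrases in the
    exhaustive-history parsing, without length normalization.
    """
    x = np.asarray(window, float)
    if x.size < 2:
        raise ConfigurationError("LZ complexity needs at least 2 samples")
    s = (x >= np.median(x)).astype(np.uint8)
    return _lz76_phrases(s)


def _lz76_phrases(s: np.ndarray) -> int:
    # Kaspar-Schuster exhaustive-history parsing; a trailing incomplete
    # phrase counts as one phrase. u: start of the current phrase, i:
    # candidate match start in the history, v: current extension length.
    n = len(s)
    c = 1
    u = 1
    v = 1
    vmax = 1
    i = 0
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            vmax = max(v, vmax)
            i += 1
            if i == u:  # no prefix substring reproduces the extension
                c += 1
                u += vmax
                v = 1
                i = 0
                vmax = 1
            else:
                v = 1
    if v != 1:
        c += 1
    return c


def fractal_dimensions(window: np.ndarray, kmax: int = 8) -> dict:
    """Higuchi and Katz fractal dimensions of one window.

    Katz: FD = log10(m) / (log10(m) + log10(d/L)) with L the summed
    successive amplitude distances, d the largest distance from the first
    point, and m the number of steps. Higuchi: slope of log curve length
    against log(1/k) for k = 1..kmax. Constant windows return 1 for both
    with the degenerate flag set.
    """
    x = np.asarray(window, float)
    n = x.size
    diffs = np.abs(np.diff(x))
    L = float(diffs.sum())
    d = float(np.max(np.abs(x - x[0])))
    if L == 0.0 or d == 0.0:
        return {"higuchi": 1.0, "katz": 1.0, "degenerate": True}
    m = n - 1
    katz = np.log10(m) / (np.log10(m) + np.log10(d / L))

    if n < 10:
        raise ConfigurationError("Higuchi FD needs at least 10 samples")
    ks, lengths = [], []
    for k in range(1, kmax + 1):
        Lk = []
        for m0 in range(k):
            n_steps = (n - m0 - 1) // k
            if n_steps < 1:
                continue
            idx = m0 + np.arange(n_steps + 1) * k
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (n_steps * k)
            Lk.append(dist * norm / k)
        if Lk:
            mean_l = np.mean(Lk)
            if mean_l > 0:
                ks.append(k)
                lengths.append(mean_l)
    ks = np.asarray(ks, float)
    lengths = np.asarray(lengths, float)
    slope = np.polyfit(np.log(1.0 / ks), np.log(lengths), 1)[0]
    return {"higuchi": float(slope), "katz": float(katz), "degenerate": False}


def _rs_expected(n: int) -> float:
    """Anis-Lloyd expected rescaled range of white noise at segment length n."""
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        from scipy.special import gammaln

        front = np.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2.0)
    return float((n - 0.5) / n * front * s)


def hurst_exponent(window: np.ndarray) -> float:
    """Rescaled-range (R/S) Hurst exponent of one window, clipped to [0, 1].

    Mean R/S is computed over dyadic segment lengths and regressed on the
    log segment length; the small-sample bias is removed with the
    Anis-Lloyd expected R/S so white noise sits at 0.5. Degenerate
    (zero-variance) windows return 0.5.
    """
    x = np.asarray(window, float)
    n = x.size
    if n < 16:
        raise ConfigurationError("Hurst estimate needs at least 16 samples")
    sizes = []
    size = n
    while size >= 8:
        sizes.append(size)
        size //= 2
    log_rs, log_exp, log_n = [], [], []
    for size in sizes:
        n_seg = n // size
        rs_vals = []
        for s0 in range(n_seg):
            seg = x[s0 * size : (s0 + 1) * size]
            z = seg - seg.mean()
            std = z.std(ddof=0)
            if std == 0:
                continue
            y = np.cumsum(z)
            rs_vals.append((y.max() - y.min()) / std)
        if rs_vals:
            log_rs.append(np.log(np.mean(rs_vals)))
            log_exp.append(np.log(_rs_expected(size)))
            log_n.append(np.log(size))
    if len(log_rs) < 2:
        return 0.5
    slope_raw = np.polyfit(log_n, log_rs, 1)[0]
    slope_exp = np.polyfit(log_n, log_exp, 1)[0]
    return float(np.clip(0.5 + slope_raw - slope_exp, 0.0, 1.0))


def entropies(window: np.ndarray, m: int = 2, r_factor: float = 0.2) -> dict:
    """Sample entropy and approximate entropy (m = 2, r = 0.2 x SD).

    Chebyshev distance; SampEn excludes self-matches, ApEn includes them
    (Pincus phi-difference). Zero-SD windows return 0 for both, flagged;
    when no template matches at length m+1 exist, SampEn is capped at
    ln(B) + ln(2) and flagged.
    """
    x = np.asarray(window, float)
    n = x.size
    if n < 10:
        raise ConfigurationError("entropy estimates need at least 10 samples")
    sd = x.std(ddof=0)
    if sd == 0:
        return {"sample_entropy": 0.0, "approximate_entropy": 0.0, "degenerate": True}
    r = r_factor * sd

    def _count(mm: int, include_self: bool):
        n_t = n - mm + 1
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        match = d <= r
        if include_self:
            return match.sum(axis=1) / n_t  # C_i including self-match
        iu = np.triu_indices(n_t, k=1)
        return int(match[iu].sum())

    # ApEn: phi(m) - phi(m+1) with self-matches included
    c_m = _count(m, True)
    c_m1 = _count(m + 1, True)
    apen = float(np.mean(np.log(c_m)) - np.mean(np.log(c_m1)))

    B = _count(m, False)
    A = _count(m + 1, False)
    degenerate = False
    if B == 0:
        sampen = 0.0
        degenerate = True
    elif A == 0:
        sampen = float(np.log(B) + np.log(2.0))
        degenerate = True
    else:
        sampen = float(-np.log(A / B))
    return {
        "sample_entropy": sampen,
        "approximate_entropy": apen,
        "degenerate": degenerate,
    }


def autocorrelation(window: np.ndarray, lag: int) -> float:
    """Pearson correlation of the window with its lag-shifted copy.

    Computed over the w - lag overlapping samples; zero variance in either
    segment yields 0.
    """
    x = np.asarray(window, float)
    w = x.size
    if not (1 <= lag <= w // 2):
        raise ConfigurationError(f"lag must be in [1, w/2]; got {lag} for w={w}")
    a, b = x[:-lag], x[lag:]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def default_ac_lag(fs: float) -> int:
    """Default autocorrelation lag: 10 ms at the given sampling rate."""
    return max(1, round_half_up(10.0 * fs / 1000.0))


def hjorth(window: np.ndarray) -> dict:
    """Hjorth mobility and complexity from first differences.

    Mobility = sqrt(var(dx)/var(x)) measures spectral width; complexity =
    mobility(dx)/mobility(x). Zero-variance windows return 0 for both.
    """
    x = np.asarray(window, float)
    if x.size < 3:
        raise ConfigurationError("Hjorth parameters need at least 3 samples")
    dx = np.diff(x)
    ddx = np.diff(dx)
    v0, v1, v2 = x.var(), dx.var(), ddx.var()
    if v0 == 0 or v1 == 0:
        return {"mobility": 0.0, "complexity": 0.0, "degenerate": True}
    mob = np.sqrt(v1 / v0)
    return {
        "mobility": float(mob),
        "complexity": float(np.sqrt(v2 / v1) / mob),
        "degenerate": False,
    }


def spectral_summary(window: np.ndarray, fs: float) -> dict:
    """Periodogram-based spectral summaries of the mean-removed window.

    Rectangular-window periodogram; mean frequency is the power-weighted
    mean, the median frequency and 95% spectral edge are cumulative-power
    quantiles, the zero-crossing rate counts sign changes, signal power is
    the mean squared amplitude, and power/phase at the median frequency are
    read from the discrete spectrum bin nearest that frequency.
    """
    x = np.asarray(window, float)
    w = x.size
    if w < 8:
        raise ConfigurationError("spectral summary needs at least 8 samples")
    xm = x - x.mean()
    power_total = float(np.mean(xm**2))
    s = np.sign(xm)
    s = s[s != 0]
    zc = int(np.count_nonzero(np.diff(s)))
    if power_total == 0.0:
        return {
            "mean_frequency": 0.0,
            "median_frequency": 0.0,
            "zero_crossings": 0.0,
            "sef95": 0.0,
            "signal_power": 0.0,
            "power_at_median_freq": 0.0,
            "phase_at_median_freq": 0.0,
            "degenerate": True,
        }
    spec = np.fft.rfft(xm)
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    pxx = np.abs(spec) ** 2
    total = pxx.sum()
    cum = np.cumsum(pxx) / total
    med_f = float(freqs[np.searchsorted(cum, 0.5)])
    sef = float(freqs[np.searchsorted(cum, 0.95)])
    mean_f = float((freqs * pxx).sum() / total)
    bin_idx = int(np.argmin(np.abs(freqs - med_f)))
    return {
        "mean_frequency": mean_f,
        "median_frequency": med_f,
        "zero_crossings": float(zc),
        "sef95": sef,
        "signal_power": power_total,
        "power_at_median_freq": float(pxx[bin_idx] / w),
        "phase_at_median_freq": float(np.angle(spec[bin_idx])),
        "degenerate": False,
    }


def cross_correlation_profile(window_block: np.ndarray, electrode: int) -> np.ndarray:
    """Zero-lag Pearson correlations of one electrode with every other.

    ``window_block`` is (electrodes, w); returns e-1 values ordered by the
    other electrodes' indices. Zero-variance pairs yield 0.
    """
    block = np.asarray(window_block, float)
    e = block.shape[0]
    if e < 2:
        raise ConfigurationError("cross-correlation needs at least 2 electrodes")
    xc = block - block.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    out = np.zeros(e - 1)
    others = [j for j in range(e) if j != electrode]
    for k, j in enumerate(others):
        denom = norms[electrode] * norms[j]
        if denom > 0:
            out[k] = float(xc[electrode] @ xc[j] / denom)
    return out


def wavelet_levels_for(w: int) -> int:
    """Decomposition depth: 5 levels for w >= 32, else reduced with warning."""
    if w >= 2**WAVELET_LEVELS:
        return WAVELET_LEVELS
    level = max(1, int(np.floor(np.log2(w))) - 1)
    warnings.warn(
        f"window of {w} samples too short for {WAVELET_LEVELS}-level wavelet "
        f"decomposition; reduced to {level} levels",
        stacklevel=2,
    )
    return level


def wavelet_features(
    window: np.ndarray, include_approximation: bool = False
) -> np.ndarray:
    """Symlet-2 DWT coefficients of one window.

    Detail coefficients D1..D5 concatenated (57 values for a 50-sample
    window under symmetric boundary extension); the level-5 approximation
    A5 is appended when ``include_approximation`` is set. Windows shorter
    than 32 samples use a reduced level count (warned, never silently
    truncated).
    """
    x = np.asarray(window, float)
    level = wavelet_levels_for(x.size)
    with warnings.catch_warnings():
        # the deliberate 5-level depth on short windows trips pywt's
        # boundary-effect advisory
        warnings.filterwarnings("ignore", message="Level value .* is too high")
        coeffs = pywt.wavedec(x, WAVELET_BASIS, mode="symmetric", level=level)
    details = coeffs[1:][::-1]  # D1 first
    parts = list(details)
    if include_approximation:
        parts.append(coeffs[0])
    return np.concatenate(parts)


def hilbert_features(window: np.ndarray) -> dict:
    """Analytic-signal amplitude envelope and instantaneous phase.

    Phase in radians wrapped to (-pi, pi]; one value per sample for each.
    """
    x = np.asarray(window, float)
    if x.size < 8:
        raise ConfigurationError("Hilbert features need at least 8 samples")
    analytic = sp_signal.hilbert(x)
    return {"amplitude": np.abs(analytic), "phase": np.angle(analytic)}


def raw_samples(window: np.ndarray) -> np.ndarray:
    """Identity copy of the window (the no-feature-extraction baseline)."""
    return np.array(window, float)


def feature_dim(
    feature_name: str,
    n_electrodes: int,
    w: int,
    include_approximation: bool = False,
) -> int:
    """Values per electrode per trial (f) for one feature."""
    if feature_name in SINGLE_VALUED:
        return 1
    if feature_name == "cross_correlation":
        return n_electrodes - 1
    if feature_name in ("hilbert_amplitude", "hilbert_phase", "samples"):
        return w
    if feature_name == "wavelet":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return wavelet_features(
                np.zeros(w), include_approximation=include_approximation
            ).size
    raise ConfigurationError(f"unknown feature {feature_name!r}")


# ---------------------------------------------------------------------------
# vectorized per-block implementations (trials x electrodes x w)


def _v_moments(block: np.ndarray) -> dict:
    var = block.var(axis=-1, ddof=1)
    mean = block.mean(axis=-1)
    xc = block - mean[..., None]
    s = block.std(axis=-1, ddof=0)
    safe = np.where(s == 0, 1.0, s)
    skew = np.mean(xc**3, axis=-1) / safe**3
    kurt = np.mean(xc**4, axis=-1) / safe**4
    zero = s == 0
    skew[zero] = 0.0
    kurt[zero] = 0.0
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": np.median(block, axis=-1),
        "degenerate": zero,
    }


def _v_hjorth(block: np.ndarray) -> dict:
    dx = np.diff(block, axis=-1)
    ddx = np.diff(dx, axis=-1)
    v0, v1, v2 = block.var(axis=-1), dx.var(axis=-1), ddx.var(axis=-1)
    bad = (v0 == 0) | (v1 == 0)
    v0s, v1s = np.where(bad, 1.0, v0), np.where(bad, 1.0, v1)
    mob = np.sqrt(v1s / v0s)
    comp = np.sqrt(np.where(bad, 0.0, v2) / v1s) / mob
    mob[bad] = 0.0
    comp[bad] = 0.0
    return {"mobility": mob, "complexity": comp, "degenerate": bad}


def _v_autocorr(block: np.ndarray, lag: int) -> np.ndarray:
    a = block[..., :-lag]
    b = block[..., lag:]
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((am**2).sum(-1) * (bm**2).sum(-1))
    out = np.zeros(block.shape[:-1])
    ok = denom > 0
    out[ok] = (am * bm).sum(-1)[ok] / denom[ok]
    return out


def _v_spectral(block: np.ndarray, fs: float) -> dict:
    w = block.shape[-1]
    xm = block - block.mean(axis=-1, keepdims=True)
    power_total = np.mean(xm**2, axis=-1)
    sgn = np.sign(xm)
    # treat exact zeros as continuing the previous sign (matches the
    # scalar op's drop-zeros rule for the windows that matter)
    zc = np.zeros(block.shape[:-1])
    flat_idx = np.ndindex(*block.shape[:-1])
    for idx in flat_idx:
        s = sgn[idx]
        s = s[s != 0]
        zc[idx] = np.count_nonzero(np.diff(s))
    spec = np.fft.rfft(xm, axis=-1)
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    pxx = np.abs(spec) ** 2
    total = pxx.sum(axis=-1)
    bad = total == 0
    total_s = np.where(bad, 1.0, total)
    cum = np.cumsum(pxx, axis=-1) / total_s[..., None]
    nf = freqs.size
    med_idx = np.apply_along_axis(lambda c: np.searchsorted(c, 0.5), -1, cum)
    sef_idx = np.apply_along_axis(lambda c: np.searchsorted(c, 0.95), -1, cum)
    med_idx = np.minimum(med_idx, nf - 1)  # zero-power rows: masked below
    sef_idx = np.minimum(sef_idx, nf - 1)
    med_f = freqs[med_idx]
    sef = freqs[sef_idx]
    mean_f = (freqs * pxx).sum(-1) / total_s
    p_med = np.take_along_axis(pxx, med_idx[..., None], axis=-1)[..., 0] / w
    ph_med = np.take_along_axis(np.angle(spec), med_idx[..., None], axis=-1)[..., 0]
    for arr in (med_f, sef, mean_f, p_med, ph_med):
        arr[bad] = 0.0
    return {
        "mean_frequency": mean_f,
        "median_frequency": med_f,
        "zero_crossings": zc,
        "sef95": sef,
        "signal_power": power_total,
        "power_at_median_freq": p_med,
        "phase_at_median_freq": ph_med,
        "degenerate": bad,
    }


def _loop_single(block: np.ndarray, func) -> tuple[np.ndarray, np.ndarray]:
    n, e, _ = block.shape
    out = np.empty((n, e))
    flags = np.zeros((n, e), bool)
    for i in range(n):
        for j in range(e):
            res = func(block[i, j])
            if isinstance(res, tuple):
                out[i, j], flags[i, j] = res
            else:
                out[i, j] = res
    return out, flags


_SPECTRAL_KEYS = (
    "mean_frequency",
    "median_frequency",
    "zero_crossings",
    "sef95",
    "signal_power",
    "power_at_median_freq",
    "phase_at_median_freq",
)
_MOMENT_KEYS = ("mean", "variance", "skewness", "kurtosis", "median")


def _single_valued_block(
    feature_name: str, block: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """(n, e) values and degeneracy flags for one single-valued feature."""
    if feature_name in _MOMENT_KEYS:
        m = _v_moments(block)
        return m[feature_name], m["degenerate"]
    if feature_name in ("hjorth_mobility", "hjorth_complexity"):
        h = _v_hjorth(block)
        key = "mobility" if feature_name == "hjorth_mobility" else "complexity"
        return h[key], h["degenerate"]
    if feature_name == "autocorrelation":
        lag = default_ac_lag(fs)
        lag = min(lag, block.shape[-1] // 2)
        return _v_autocorr(block, lag), np.zeros(block.shape[:-1], bool)
    if feature_name in _SPECTRAL_KEYS:
        s = _v_spectral(block, fs)
        return s[feature_name], s["degenerate"]
    if feature_name == "lempel_ziv":
        return _loop_single(block, lambda x: float(lz_complexity(x)))
    if feature_name in ("higuchi_fd", "katz_fd"):
        key = "higuchi" if feature_name == "higuchi_fd" else "katz"

        def f(x):
            r = fractal_dimensions(x)
            return r[key], r["degenerate"]

        return _loop_single(block, f)
    if feature_name == "hurst":
        return _loop_single(
            block, lambda x: (hurst_exponent(x), bool(x.std() == 0))
        )
    if feature_name in ("sample_entropy", "approx_entropy"):
        key = (
            "sample_entropy"
            if feature_name == "sample_entropy"
            else "approximate_entropy"
        )

        def f(x):
            r = entropies(x)
            return r[key], r["degenerate"]

        return _loop_single(block, f)
    raise ConfigurationError(f"unknown single-valued feature {feature_name!r}")


def _multi_valued_block(
    feature_name: str, block: np.ndarray, include_approximation: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(n, e*f) values (electrode-major) and (n, e) flags."""
    n, e, w = block.shape
    flags = np.zeros((n, e), bool)
    if feature_name == "samples":
        return block.reshape(n, e * w), flags
    if feature_name in ("hilbert_amplitude", "hilbert_phase"):
        analytic = sp_signal.hilbert(block, axis=-1)
        arr = (
            np.abs(analytic)
            if feature_name == "hilbert_amplitude"
            else np.angle(analytic)
        )
        return arr.reshape(n, e * w), flags
    if feature_name == "wavelet":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            level = wavelet_levels_for(w)
            coeffs = pywt.wavedec(block, WAVELET_BASIS, mode="symmetric",
                                  level=level, axis=-1)
        parts = list(coeffs[1:][::-1])
        if include_approximation:
            parts.append(coeffs[0])
        arr = np.concatenate(parts, axis=-1)
        return arr.reshape(n, e * arr.shape[-1]), flags
    if feature_name == "cross_correlation":
        xc = block - block.mean(axis=-1, keepdims=True)
        norms = np.sqrt((xc**2).sum(-1))  # (n, e)
        prods = np.einsum("new,nfw->nef", xc, xc)
        denom = norms[:, :, None] * norms[:, None, :]
        corr = np.zeros_like(prods)
        ok = denom > 0
        corr[ok] = prods[ok] / denom[ok]
        flags = norms == 0
        # drop the self-correlation diagonal, keep electrode order
        keep = ~np.eye(e, dtype=bool)
        out = corr[:, keep].reshape(n, e * (e - 1))
        return out, flags
    raise ConfigurationError(f"unknown multi-valued feature {feature_name!r}")


def extract_feature_tensor(
    dataset: EpochedDataset,
    spec: WindowSpec,
    feature_name: str,
    include_approximation: bool = False,
    baseline: bool = True,
) -> list[FeatureMatrix]:
    """Extract one feature at every sliding window of a dataset.

    Pre-stimulus baseline correction (mean of t < 0 per trial and
    electrode) is applied once beforehand. Returns one
    :class:`FeatureMatrix` per window; degenerate-window counts are kept
    in each matrix's ``meta`` and values are always finite.
    """
    if feature_name not in ALL_FEATURES:
        raise ConfigurationError(
            f"unknown feature {feature_name!r}; valid names: {sorted(ALL_FEATURES)}"
        )
    if baseline:
        t0 = dataset.t_first_sample
        dataset = baseline_correct(dataset, (max(t0, -200.0), 0.0))
    e = dataset.n_electrodes
    out = []
    for center, block in sliding_windows(dataset, spec):
        if feature_name in SINGLE_VALUED:
            vals, flags = _single_valued_block(feature_name, block, dataset.fs)
            f = 1
            vals = vals.reshape(block.shape[0], e)
        else:
            vals, flags = _multi_valued_block(
                feature_name, block, include_approximation
            )
            f = vals.shape[1] // e
        out.append(
            FeatureMatrix(
                feature_name=feature_name,
                window_center=center,
                values=vals,
                f=f,
                n_electrodes=e,
                meta={"n_degenerate": int(np.count_nonzero(flags))},
            )
        )
    return out
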