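"""Synthetic epoched-EEG cohorts with ground-truth category codes.

Each simulated trial is 1/f ("pink") background noise plus a common
Gaussian-envelope evoked response (ERP). Category information is injected
through one of four encoding codes, mixed into the electrodes through fixed
spatial loadings and a per-participant gain:

``mean``
    A sustained amplitude offset proportional to the category index is
    added under a flat-top envelope spanning the ERP, so the within-window
    mean carries the code while the within-window variance stays matched
    (a sharply peaked envelope would leak into variance).
``variance``
    Extra zero-mean noise is added inside the ERP envelope with a
    category-dependent SD, so window variance differs while window means
    match across categories.
``frequency``
    A fixed-amplitude sinusoid (random phase per trial) whose frequency
    differs by category in 10 Hz steps, so spectral features carry the
    code while mean and variance are matched (the spacing must be
    resolvable inside one 50 ms analysis window).
``multiscale``
    Short oscillatory bursts at a category-specific dyadic scale
    (duration ``2**level`` samples) at fixed latencies with fixed sign,
    energy-matched across categories: the class difference lives in
    *which temporal scale* carries the deterministic waveform, which
    scale-sensitive (wavelet-like) features see as a coefficient mean
    shift while overall amplitude and variance are matched.
``none``
    No label-dependent signal at all: labels are exchangeable (null data).

Per-participant gains ``g_p ~ lognormal(0, 0.25)`` make decodability vary
across simulated participants, which is what lets reaction times (generated
with a negative link to the gain) correlate with decoding accuracy.
Everything is a pure function of ``(config, seed, participant_index)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import ConfigurationError, EpochedDataset
from .windows import round_half_up

__all__ = [
    "SyntheticConfig",
    "generate_participant",
    "generate_cohort",
    "attach_reaction_times",
]

CODES = ("mean", "variance", "frequency", "multiscale", "none")

# SeedSequence stream tags: keep the per-purpose RNG streams independent.
_GAIN_STREAM = 7919
_STRUCT_STREAM = 104729
_TRIAL_STREAM = 1299709
_RT_STREAM = 15485863


@dataclass
class SyntheticConfig:
    """Study conditions for a simulated cohort.

    The defaults mirror a desk-scale version of the study setup: 10
    participants, 4 categories, epochs of -200..+1000 ms. ``effect_size``
    is dimensionless (scales with ``noise_sd``); ``rt_link`` maps the
    per-participant gain to a mean reaction time as
    ``intercept - slope * g_p`` plus Gaussian noise.
    """

    n_participants: int = 10
    n_categories: int = 4
    trials_per_category: int = 30
    n_electrodes: int = 16
    fs: float = 250.0
    epoch_span: tuple[float, float] = (-200.0, 1000.0)
    code: str = "none"
    effect_size: float = 0.0
    noise_sd: float = 10.0
    pink_exponent: float = 1.0
    spatial_loadings: np.ndarray | None = None
    erp_latency: float = 150.0
    erp_width: float = 40.0
    erp_amp: float = 5.0
    rt_link: dict = field(
        default_factory=lambda: {"intercept": 1146.0, "slope": 200.0, "noise_sd": 50.0}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_categories < 2:
            raise ConfigurationError("need at least 2 categories")
        if self.trials_per_category < 2:
            raise ConfigurationError("need at least 2 trials per category")
        if self.n_electrodes < 1 or self.n_participants < 1:
            raise ConfigurationError("electrode and participant counts must be >= 1")
        pre, post = self.epoch_span
        if not (pre < 0.0 < post):
            raise ConfigurationError("epoch_span must bracket stimulus onset (0 ms)")
        if round_half_up(50.0 * self.fs / 1000.0) < 8:
            raise ConfigurationError(
                f"fs={self.fs} Hz yields < 8 samples in a 50 ms analysis window"
            )
        if self.code not in CODES:
            raise ConfigurationError(f"unknown code {self.code!r}; valid: {CODES}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.trials_per_category < 20:
            warnings.warn(
                "trials_per_category < 2 x 10 folds; cross-validation folds "
                "may be fragile",
                stacklevel=2,
            )
        if self.spatial_loadings is not None:
            sl = np.asarray(self.spatial_loadings, float)
            if sl.shape != (self.n_electrodes,):
                raise ConfigurationError("spatial_loadings must have one weight per electrode")
            if sl.min() < 0 or sl.max() > 1:
                raise ConfigurationError("spatial_loadings must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        pre, post = self.epoch_span
        return round_half_up((post - pre) * self.fs / 1000.0)

    @property
    def times(self) -> np.ndarray:
        return self.epoch_span[0] + np.arange(self.n_samples) * 1000.0 / self.fs


def _loadings(config: SyntheticConfig, seed: int) -> np.ndarray:
    if config.spatial_loadings is not None:
        return np.asarray(config.spatial_loadings, float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STRUCT_STREAM]))
    return rng.uniform(0.3, 1.0, config.n_electrodes)


def participant_gain(config: SyntheticConfig, participant_index: int, seed: int) -> float:
    """Per-participant lognormal(0, 0.25) gain; unit median, strictly positive."""
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _GAIN_STREAM, participant_index])
    )
    return float(rng.lognormal(mean=0.0, sigma=0.25))


def _pink_noise(rng: np.random.Generator, shape: tuple, n: int, exponent: float,
                sd: float) -> np.ndarray:
    """1/f noise by spectral shaping of white noise, per-trace SD ``sd``."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * sd


def _burst_shape(d: int) -> np.ndarray:
    """Unit-RMS Gaussian-windowed single-cycle oscillation of d samples."""
    u = (np.arange(d) + 0.5) / d
    s = np.exp(-((u - 0.5) ** 2) / (2 * 0.18**2)) * np.sin(2 * np.pi * u)
    s -= s.mean()
    return s / np.sqrt(np.mean(s**2))


def generate_participant(
    config: SyntheticConfig, participant_index: int, seed: int | None = None
) -> EpochedDataset:
    """Simulate one participant's epoched trials.

    Deterministic given ``(config, seed, participant_index)``; the seed
    defaults to ``config.seed``.
    """
    config.validate()
    if participant_index >= config.n_participants:
        raise ConfigurationError("participant_index out of range")
    seed = config.seed if seed is None else seed

    n = config.n_samples
    t = config.times
    e = config.n_electrodes
    n_trials = config.n_categories * config.trials_per_category
    loadings = _loadings(config, seed)
    g = participant_gain(config, participant_index, seed)

    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _TRIAL_STREAM, participant_index])
    )
    labels = rng.permutation(
        np.repeat(np.arange(config.n_categories), config.trials_per_category)
    )

    data = _pink_noise(rng, (n_trials, e), n, config.pink_exponent, config.noise_sd)

    env = np.exp(-((t - config.erp_latency) ** 2) / (2 * config.erp_width**2))
    erp = config.erp_amp * env  # common evoked response, shape (n,)
    data += g * loadings[None, :, None] * erp[None, None, :]

    es = config.effect_size
    if config.code != "none" and es != 0.0:
        cat = labels.astype(float)  # category index per trial
        mix = g * loadings[None, :, None]
        if config.code == "mean":
            # flat-top envelope spanning the ERP region: the offset is
            # locally constant inside a 50 ms window, so it moves the
            # window mean without touching the window variance
            lo = config.erp_latency - 2 * config.erp_width
            hi = config.erp_latency + 4 * config.erp_width
            edge = config.erp_width / 2.0
            plateau = 0.5 * (
                np.tanh((t - lo) / edge) - np.tanh((t - hi) / edge)
            )
            amp = es * config.noise_sd * cat
            data += mix * amp[:, None, None] * plateau[None, None, :]
        elif config.code == "variance":
            # SD multiplier 1 + es*cat inside the envelope; added noise is
            # zero-mean so category means agree by construction.
            mult = 1.0 + es * cat
            extra_sd = config.noise_sd * np.sqrt(np.maximum(mult**2 - 1.0, 0.0))
            extra = rng.standard_normal((n_trials, e, n))
            data += mix * extra_sd[:, None, None] * env[None, None, :] * extra
        elif config.code == "frequency":
            # 10 Hz category spacing: resolvable within one 50 ms window
            freq = 10.0 + 10.0 * cat
            amp = es * config.noise_sd  # fixed amplitude: variance-matched
            phase = rng.uniform(0, 2 * np.pi, n_trials)
            tone = np.sin(
                2 * np.pi * freq[:, None] * t[None, :] / 1000.0 + phase[:, None]
            )
            data += mix * amp * env[None, None, :] * tone[:, None, :]
        elif config.code == "multiscale":
            # Deterministic bursts at a category-specific dyadic scale,
            # fixed latencies and sign, per-burst energy normalized so the
            # total added variance matches across categories: the class
            # difference is the temporal scale of the waveform, not its
            # amplitude.
            ref_len = 16.0
            dt = 1000.0 / config.fs
            centers_ms = config.erp_latency + np.array([-1.5, 0.0, 1.5]) * (
                2 * config.erp_width
            )
            waves = {}
            for c in range(config.n_categories):
                level = c + 2
                d = min(2**level, n // 2)
                shape = _burst_shape(d)
                amp = es * config.noise_sd * np.sqrt(ref_len / d)
                wave = np.zeros(n)
                for t0 in centers_ms:
                    start = int(np.clip(round((t0 - t[0]) / dt) - d // 2, 0, n - d))
                    wave[start : start + d] += amp * shape
                waves[c] = wave
            for i in range(n_trials):
                data[i] += g * loadings[:, None] * waves[int(labels[i])][None, :]

    return EpochedDataset(
        data=data,
        labels=labels,
        fs=config.fs,
        t_first_sample=config.epoch_span[0],
        participant_id=f"sub-{participant_index:02d}",
        category_names=[f"cat{i}" for i in range(config.n_categories)],
        meta={"gain": g, "seed": seed, "code": config.code},
    )


def generate_cohort(config: SyntheticConfig) -> list[EpochedDataset]:
    """Simulate all participants; per-participant gains stored in ``meta``."""
    config.validate()
    return [
        generate_participant(config, i, config.seed)
        for i in range(config.n_participants)
    ]


def attach_reaction_times(
    cohort: list[EpochedDataset], config: SyntheticConfig, seed: int | None = None
) -> list[EpochedDataset]:
    """Attach per-trial reaction times negatively linked to decodability.

    Participant mean RT = ``intercept - slope * g_p`` plus Gaussian noise
    (SD ``rt_link['noise_sd']``); trial RTs are jittered around the
    participant mean with the same SD and clipped to a 100 ms floor.
    """
    seed = config.seed if seed is None else seed
    link = config.rt_link
    out = []
    for i, ds in enumerate(cohort):
        if "gain" not in ds.meta:
            raise ConfigurationError(
                "cohort datasets lack stored gains; use generate_cohort first"
            )
        rng = np.random.default_rng(np.random.SeedSequence([seed, _RT_STREAM, i]))
        mean_rt = (
            link["intercept"]
            - link["slope"] * ds.meta["gain"]
            + rng.normal(0.0, link["noise_sd"])
        )
        rt = mean_rt + rng.normal(0.0, link["noise_sd"], ds.n_trials)
        rt = np.maximum(rt, 100.0)
        out.append(ds.replace(rt=rt))
    return out
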