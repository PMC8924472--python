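"""Bayesian and behavioral evaluation of decoding curves.

Evidence that post-stimulus decoding exceeds the participant-wise
pre-stimulus baseline is quantified with the JZS Bayes factor t-test: the
effect size carries a zero-centered Cauchy prior (scale r = sqrt(2)/2,
the common default), which is equivalent to an inverse-gamma mixture over
the g-prior, and BF10 is evaluated by adaptive numerical quadrature over
g. Conventional evidence categories are applied (BF10 > 10 / > 3 strong /
moderate for a difference; < 1/10 / < 1/3 the same for the null), and no
multiplicity correction is applied to Bayes factors.

Behavioral relevance is the across-participant Spearman correlation
between window-wise decoding accuracy and mean reaction time, tested
against a permutation null (RT vector shuffled across participants,
one-sided in the observed direction, add-one smoothed) with positive-FDR
q-values across time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .datasets import ConfigurationError
from .decoding import DecodingCurve

__all__ = [
    "BayesSeries",
    "CurveParams",
    "BehaviorCorrSeries",
    "jzs_bf_ttest",
    "categorize_evidence",
    "evidence_series",
    "curve_parameters",
    "brain_behavior_correlation",
    "permutation_pvalues",
    "fdr_correct",
]

JZS_SCALE = math.sqrt(2.0) / 2.0

EVIDENCE_LEVELS = ("strong_H1", "moderate_H1", "insufficient", "moderate_H0", "strong_H0")


@dataclass
class BayesSeries:
    window_centers: np.ndarray
    bf: np.ndarray  # BF10 per window
    evidence: list[str]


@dataclass
class CurveParams:
    """Per-participant summaries of a decoding curve (post-stimulus)."""

    max_acc: np.ndarray
    mean_acc: np.ndarray
    t_max: np.ndarray  # ms
    t_onset: np.ndarray  # ms; NaN when never sustained above chance


@dataclass
class BehaviorCorrSeries:
    window_centers: np.ndarray
    rho: np.ndarray
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    significant: np.ndarray | None = None


def _tstat(x: np.ndarray, y: np.ndarray, paired: bool) -> tuple[float, int, float]:
    """(t, df, effective N) for the JZS integral."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if x.size != y.size:
            raise ConfigurationError("paired test needs equal-length samples")
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            raise ConfigurationError("zero variance in paired differences")
        n = d.size
        return float(d.mean() / (sd / math.sqrt(n))), n - 1, float(n)
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / df)
    if sp == 0:
        raise ConfigurationError("zero within-sample variance in both samples")
    t = (x.mean() - y.mean()) / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    return float(t), df, float(n1 * n2 / (n1 + n2))


def jzs_bf_ttest(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool = False,
    r: float = JZS_SCALE,
) -> float:
    """JZS Bayes factor (BF10) for a two-sample or paired t-test.

    Marginalizes the g-prior representation of the Cauchy effect-size
    prior by adaptive quadrature:

        BF10 = int_0^inf (1+Ng)^(-1/2) (1 + t^2/(nu(1+Ng)))^(-(nu+1)/2)
               pi(g) dg  /  (1 + t^2/nu)^(-(nu+1)/2)

    with pi(g) the inverse-gamma(1/2, r^2/2) density, nu the degrees of
    freedom and N the effective sample size. BF10 > 1 favors a difference.
    """
    if np.asarray(x).size < 2 or np.asarray(y).size < 2:
        raise ConfigurationError("each sample needs at least 2 values")
    t, nu, N = _tstat(x, y, paired)

    log_h0 = -(nu + 1) / 2.0 * math.log1p(t * t / nu)

    def integrand(g: float) -> float:
        log_lik = (
            -0.5 * math.log1p(N * g)
            - (nu + 1) / 2.0 * math.log1p(t * t / (nu * (1.0 + N * g)))
        )
        log_prior = (
            math.log(r) - 0.5 * math.log(2 * math.pi) - 1.5 * math.log(g)
            - r * r / (2.0 * g)
        )
        return math.exp(log_lik + log_prior - log_h0)

    bf10, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(bf10)


def categorize_evidence(bf: float) -> str:
    """Map BF10 to the conventional evidence category."""
    if bf > 10:
        return "strong_H1"
    if bf > 3:
        return "moderate_H1"
    if bf < 0.1:
        return "strong_H0"
    if bf < 1.0 / 3.0:
        return "moderate_H0"
    return "insufficient"


def evidence_series(
    curve: DecodingCurve, baseline_window: tuple[float, float] = (-200.0, 0.0)
) -> BayesSeries:
    """BF10 per post-stimulus window against the pre-stimulus baseline.

    The baseline is each participant's mean accuracy over pre-stimulus
    windows; each post-stimulus window's accuracies are compared against
    that vector with the (unpaired) JZS t-test. No multiple-comparison
    correction is applied.
    """
    t = curve.window_centers
    pre = (t >= baseline_window[0]) & (t < baseline_window[1])
    post = t >= baseline_window[1]
    if not pre.any():
        raise ConfigurationError("curve has no pre-stimulus baseline windows")
    baseline = curve.accuracy[:, pre].mean(axis=1)
    bfs = np.array(
        [jzs_bf_ttest(curve.accuracy[:, wi], baseline) for wi in np.flatnonzero(post)]
    )
    return BayesSeries(
        window_centers=t[post],
        bf=bfs,
        evidence=[categorize_evidence(b) for b in bfs],
    )


def curve_parameters(
    curve: DecodingCurve, chance: float = 0.5, sustain: int = 5
) -> CurveParams:
    """Per-participant post-stimulus decoding-curve summaries.

    Maximum and mean accuracy, time of maximum (first window on ties) and
    onset time: the first window whose accuracy exceeds chance for at
    least ``sustain`` consecutive windows (25 ms at the 5 ms step), NaN if
    never.
    """
    t = curve.window_centers
    post = t > 0
    if not post.any():
        raise ConfigurationError("curve has no post-stimulus windows")
    acc = curve.accuracy[:, post]
    tp = t[post]
    n_p = acc.shape[0]
    t_onset = np.full(n_p, np.nan)
    for i in range(n_p):
        above = acc[i] > chance
        run = 0
        for wi, a in enumerate(above):
            run = run + 1 if a else 0
            if run >= sustain:
                t_onset[i] = tp[wi - sustain + 1]
                break
    return CurveParams(
        max_acc=acc.max(axis=1),
        mean_acc=acc.mean(axis=1),
        t_max=tp[np.argmax(acc, axis=1)],
        t_onset=t_onset,
    )


def brain_behavior_correlation(
    curve: DecodingCurve, rt: np.ndarray
) -> BehaviorCorrSeries:
    """Across-participant Spearman rho between accuracy and mean RT, per window."""
    rt = np.asarray(rt, float)
    if rt.size != curve.accuracy.shape[0]:
        raise ConfigurationError("need one mean RT per participant")
    if rt.size < 5:
        raise ConfigurationError("need at least 5 participants for correlation")
    if np.unique(rt).size == 1:
        raise ConfigurationError("constant RT vector: correlation undefined")
    rho = np.array(
        [
            sp_stats.spearmanr(curve.accuracy[:, wi], rt).statistic
            for wi in range(curve.accuracy.shape[1])
        ]
    )
    return BehaviorCorrSeries(window_centers=curve.window_centers, rho=rho)


def permutation_pvalues(
    series: BehaviorCorrSeries,
    curve: DecodingCurve,
    rt: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    two_sided: bool = True,
) -> np.ndarray:
    """Permutation p-values for the brain-behavior correlations.

    The null at each window is the Spearman rho under ``n_perm`` seeded
    shuffles of the RT vector across participants; the tail is evaluated
    in the observed direction (positive or negative rho), with add-one
    smoothing so p is never zero. Because the direction is chosen after
    seeing the data, the raw directional p lives on (0, 1/2] under the
    null; with ``two_sided`` (the default) it is doubled and capped at 1,
    which restores the uniform null required by the FDR step.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be at least 100")
    rt = np.asarray(rt, float)
    n = rt.size
    rng = np.random.default_rng(seed)
    acc_ranks = np.apply_along_axis(sp_stats.rankdata, 0, curve.accuracy)
    rt_ranks = sp_stats.rankdata(rt)
    perms = np.array([rng.permutation(rt_ranks) for _ in range(n_perm)])

    def _corr(rank_matrix: np.ndarray, rank_vecs: np.ndarray) -> np.ndarray:
        a = rank_matrix - rank_matrix.mean(axis=0, keepdims=True)
        b = rank_vecs - rank_vecs.mean(axis=1, keepdims=True)
        num = b @ a  # (n_perm, n_windows)
        denom = np.sqrt((b**2).sum(axis=1))[:, None] * np.sqrt((a**2).sum(axis=0))[None]
        denom[denom == 0] = np.inf
        return num / denom

    null = _corr(acc_ranks, perms)
    obs = series.rho
    p = np.empty(obs.size)
    for wi, r_obs in enumerate(obs):
        if r_obs >= 0:
            count = int(np.sum(null[:, wi] >= r_obs))
        else:
            count = int(np.sum(null[:, wi] <= r_obs))
        p[wi] = (count + 1) / (n_perm + 1)
    if two_sided:
        p = np.minimum(2.0 * p, 1.0)
    return p


def fdr_correct(p: np.ndarray, alpha: float = 0.05, lam: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Positive-FDR q-values (Storey, lambda = 0.5) with BH fallback.

    pi0 is estimated as #{p > lambda} / ((1 - lambda) m); when the
    estimate is degenerate (no p-values above lambda, as can happen for
    short series with strong effects), the Benjamini-Hochberg step-up
    q-values are used instead. Returns (q, significance mask at q < alpha).
    """
    p = np.asarray(p, float)
    if (p <= 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in (0, 1]")
    m = p.size
    n_above = int(np.sum(p > lam))
    if n_above == 0:
        q = multipletests(p, method="fdr_bh")[1]
        return q, q < alpha
    pi0 = min(1.0, n_above / ((1.0 - lam) * m))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < alpha
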