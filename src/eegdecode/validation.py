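"""Calibration and recovery suites over synthetic cohorts.

These are the property-based evaluations the package's correctness
arguments rest on, run at desk scale:

* *null calibration* — on cohorts with no category code, group-mean
  decoding must stay inside the central 95% binomial chance band and
  Bayes factors must almost never report strong evidence;
* *code-feature specificity* — each encoding code must be decodable by
  its matched feature family and invisible to the mismatched one;
* *behavior recovery* — when reaction times are linked to decodability,
  the permutation-tested Spearman correlation must recover FDR-significant
  negative correlations inside the informative latency band, none before
  stimulus onset, and nothing anywhere when the link is absent.

Study conditions (cohort geometry, effect sizes, RT link) come from the
committed calibration fixture (``data/calibration.json``), fixed once by a
pilot sweep.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
from scipy.stats import binom

from .decoding import run_study
from .stats import (
    brain_behavior_correlation,
    evidence_series,
    fdr_correct,
    permutation_pvalues,
)
from .synth import SyntheticConfig, attach_reaction_times, generate_cohort
from .windows import WindowSpec

__all__ = [
    "load_calibration",
    "chance_band",
    "null_calibration",
    "code_specificity",
    "behavior_recovery",
]


def load_calibration() -> dict:
    with resources.files("eegdecode.data").joinpath("calibration.json").open() as fh:
        return json.load(fh)


def _seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence([base, *key]).generate_state(1)[0] % (2**31))


def chance_band(n_eff: int, level: float = 0.95) -> tuple[float, float]:
    """Central binomial band around 0.5 for an accuracy over n_eff trials."""
    lo, hi = binom.ppf([(1 - level) / 2, (1 + level) / 2], n_eff, 0.5) / n_eff
    return float(lo), float(hi)


def null_calibration(
    base_seed: int,
    n_seeds: int = 20,
    calib: dict | None = None,
    window: WindowSpec | None = None,
) -> dict:
    """Decode code-free cohorts and measure chance/evidence calibration.

    The chance band is computed on the number of *distinct* trial
    predictions per group mean (participants x trials): each trial is
    re-used in ``n_categories - 1`` pairs, so the naive participants x
    pairs x trials count would understate the variance of the pair-
    averaged accuracy.
    """
    calib = calib or load_calibration()
    window = window or WindowSpec(**calib["window"])
    params = calib["null_cohort"]
    group_means = []
    strong = 0
    n_bf = 0
    for s in range(n_seeds):
        cfg = SyntheticConfig(code="none", effect_size=0.0,
                              seed=_seed(base_seed, 11, s), **params)
        cohort = generate_cohort(cfg)
        curves, _ = run_study(cohort, ["mean"], window, seed=_seed(base_seed, 12, s))
        curve = curves["mean"]
        group_means.append(curve.accuracy.mean(axis=0))
        bf = evidence_series(curve).bf
        strong += int((bf > 10).sum())
        n_bf += bf.size
    A = np.vstack(group_means)
    n_eff = (
        params["n_participants"]
        * params["n_categories"]
        * params["trials_per_category"]
    )
    lo, hi = chance_band(n_eff)
    return {
        "frac_within_band": float(((A >= lo) & (A <= hi)).mean()),
        "frac_strong_bf": strong / n_bf,
        "band": (lo, hi),
        "grand_mean": float(A.mean()),
        "n_windows": int(A.size),
        "n_bf_windows": n_bf,
    }


# intended / mismatched feature per encoding code
SPECIFICITY_PLAN = {
    "mean": ("mean", "variance"),
    "variance": ("variance", "mean"),
    "multiscale": ("wavelet", "mean"),
}


def code_specificity(
    base_seed: int,
    n_seeds: int = 10,
    codes: tuple[str, ...] = ("mean", "variance", "multiscale"),
    calib: dict | None = None,
) -> dict:
    """Band accuracy of the matched vs mismatched feature per code.

    Returns per code: arrays (one entry per seed) of mean accuracy inside
    the informative latency band for the intended ("on") and mismatched
    ("off") features, plus the pre-stimulus accuracy of the intended one.
    """
    calib = calib or load_calibration()
    window = WindowSpec(**calib["window"])
    lo_ms, hi_ms = calib["informative_band_ms"]
    out: dict[str, dict] = {}
    for code in codes:
        on_feat, off_feat = SPECIFICITY_PLAN[code]
        es = calib["effect_size"][code]
        on, off, pre = [], [], []
        for s in range(n_seeds):
            cfg = SyntheticConfig(
                code=code, effect_size=es, seed=_seed(base_seed, 21, s),
                **calib["cohort"],
            )
            cohort = generate_cohort(cfg)
            curves, _ = run_study(
                cohort, [on_feat, off_feat], window,
                seed=_seed(base_seed, 22, s),
            )
            t = curves[on_feat].window_centers
            band = (t > lo_ms) & (t < hi_ms)
            on.append(curves[on_feat].accuracy[:, band].mean())
            off.append(curves[off_feat].accuracy[:, band].mean())
            pre.append(curves[on_feat].accuracy[:, t < 0].mean())
        out[code] = {
            "on": np.array(on),
            "off": np.array(off),
            "pre": np.array(pre),
            "features": (on_feat, off_feat),
        }
    return out


def behavior_recovery(
    base_seed: int,
    slope: float,
    n_seeds: int = 20,
    n_perm: int = 1000,
    calib: dict | None = None,
) -> list[dict]:
    """Decode RT-linked cohorts and test the brain-behavior correlation.

    Returns one record per seed with counts of FDR-significant windows:
    negative inside the informative band, pre-stimulus, and total.
    """
    calib = calib or load_calibration()
    window = WindowSpec(**calib["window"])
    lo_ms, hi_ms = calib["informative_band_ms"]
    params = dict(calib["behavior"])
    code = params.pop("code")
    es = params.pop("effect_size")
    rt_link = dict(params.pop("rt_link"))
    rt_link["slope"] = slope
    records = []
    for s in range(n_seeds):
        cfg = SyntheticConfig(
            code=code, effect_size=es, rt_link=rt_link,
            seed=_seed(base_seed, 31, s), **params,
        )
        cohort = attach_reaction_times(generate_cohort(cfg), cfg)
        curves, _ = run_study(
            cohort, [code], window, seed=_seed(base_seed, 32, s)
        )
        curve = curves[code]
        rt = np.array([ds.rt.mean() for ds in cohort])
        series = brain_behavior_correlation(curve, rt)
        p = permutation_pvalues(
            series, curve, rt, n_perm=n_perm, seed=_seed(base_seed, 33, s)
        )
        q, sig = fdr_correct(p)
        t = curve.window_centers
        band = (t > lo_ms) & (t < hi_ms)
        records.append(
            {
                "neg_sig_band": int((sig & band & (series.rho < 0)).sum()),
                "pre_sig": int((sig & (t < 0)).sum()),
                "any_sig": int(sig.sum()),
                "n_pre_windows": int((t < 0).sum()),
                "n_windows": int(t.size),
                "min_band_rho": float(series.rho[band].min()),
            }
        )
    return records
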