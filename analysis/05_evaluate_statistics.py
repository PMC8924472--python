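"""Bayesian evidence, curve parameters and brain-behavior correlation.

Consumes the decoding curves from 03_decode_individual_features.py,
recomputes the Mean-feature curve, and writes: the JZS Bayes-factor
evidence series against the pre-stimulus baseline, the per-participant
decoding-curve parameters, and the permutation-tested, FDR-corrected
Spearman correlation between decoding accuracy and mean reaction time.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from eegdecode import WindowSpec, run_study
from eegdecode.io import (
    bayes_to_frame,
    behavior_to_frame,
    curve_params_to_frame,
    read_epochs,
)
from eegdecode.stats import (
    brain_behavior_correlation,
    curve_parameters,
    evidence_series,
    fdr_correct,
    permutation_pvalues,
)

OUT = Path("results/analysis")
SEED = 14


def main() -> None:
    cohort = [
        read_epochs(p.with_suffix(""))
        for p in sorted((OUT / "epochs").glob("*.json"))
    ]
    spec = WindowSpec(50.0, 20.0)
    curves, _ = run_study(cohort, ["mean"], spec, seed=SEED)
    curve = curves["mean"]

    bayes = evidence_series(curve)
    bayes_to_frame(bayes, "mean").to_csv(OUT / "bayes_series.csv", index=False)
    strong = bayes.window_centers[np.array(bayes.evidence) == "strong_H1"]
    if strong.size:
        print(f"strong evidence for decoding from {strong.min():+.0f} to "
              f"{strong.max():+.0f} ms ({strong.size} windows)")

    params = curve_parameters(curve)
    curve_params_to_frame(params, "mean").to_csv(
        OUT / "curve_params.csv", index=False
    )
    print(f"median max accuracy {np.median(params.max_acc):.3f}; "
          f"median onset {np.nanmedian(params.t_onset):+.0f} ms")

    rt = np.array([ds.rt.mean() for ds in cohort])
    series = brain_behavior_correlation(curve, rt)
    series.p = permutation_pvalues(series, curve, rt, n_perm=1000, seed=SEED)
    series.q, series.significant = fdr_correct(series.p)
    behavior_to_frame(series, "mean").to_csv(
        OUT / "behavior_correlation.csv", index=False
    )
    sig = series.window_centers[series.significant & (series.rho < 0)]
    if sig.size:
        print(f"significant negative decoding-RT correlation at {sig.size} "
              f"windows ({sig.min():+.0f}..{sig.max():+.0f} ms), "
              f"peak rho {series.rho.min():.2f}")
    else:
        print("no significant decoding-RT correlation")


if __name__ == "__main__":
    main()
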