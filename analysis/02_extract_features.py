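"""Extract window features for one participant of the simulated cohort.

Reads the epochs written by 01_simulate_cohort.py, extracts a
representative set of single- and multi-valued features on the 50 ms /
20 ms sliding grid, and writes a per-feature summary (dimensions,
degenerate-window counts) so the tensor layout is auditable.
"""

from pathlib import Path

import pandas as pd

from eegdecode import WindowSpec
from eegdecode.features import extract_feature_tensor
from eegdecode.io import read_epochs

OUT = Path("results/analysis")
FEATURES = ["mean", "variance", "lempel_ziv", "hjorth_mobility",
            "median_frequency", "wavelet", "samples", "cross_correlation"]


def main() -> None:
    ds = read_epochs(OUT / "epochs" / "sub-00")
    spec = WindowSpec(50.0, 20.0)
    rows = []
    for name in FEATURES:
        tensor = extract_feature_tensor(ds, spec, name)
        rows.append(
            {
                "feature": name,
                "n_windows": len(tensor),
                "f_per_electrode": tensor[0].f,
                "columns": tensor[0].values.shape[1],
                "degenerate_windows": sum(
                    fm.meta["n_degenerate"] > 0 for fm in tensor
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "feature_summary.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
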