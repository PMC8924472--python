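"""Epoch container I/O, result serialization and run manifests.

Epoched data travel as a portable pair of files: ``<prefix>.npy`` holding
the (trials, electrodes, samples) amplitude array and ``<prefix>.json``
holding the sidecar (sampling rate, epoch offset, labels, optional
reaction times, category names). Results are exported as long-format CSV
so any toolchain can consume them; every run writes a manifest recording
the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ConfigurationError, EpochedDataset
from .decoding import DecodingCurve
from .stats import BayesSeries, BehaviorCorrSeries, CurveParams

__all__ = [
    "write_epochs",
    "read_epochs",
    "config_hash",
    "write_manifest",
    "curves_to_frame",
    "bayes_to_frame",
    "behavior_to_frame",
    "curve_params_to_frame",
]


def write_epochs(dataset: EpochedDataset, prefix: str | Path) -> None:
    """Write ``<prefix>.npy`` (data) and ``<prefix>.json`` (sidecar)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(".npy"), dataset.data)
    sidecar = {
        "fs": dataset.fs,
        "t_first_sample": dataset.t_first_sample,
        "labels": dataset.labels.tolist(),
        "participant_id": dataset.participant_id,
        "rt": dataset.rt.tolist() if dataset.rt is not None else None,
        "category_names": dataset.category_names,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_epochs(prefix: str | Path) -> EpochedDataset:
    """Read an epoch container; validates shape and sidecar schema."""
    prefix = Path(prefix)
    npy = prefix.with_suffix(".npy")
    js = prefix.with_suffix(".json")
    if not npy.exists() or not js.exists():
        raise ConfigurationError(f"missing epoch container files for {prefix}")
    data = np.load(npy)
    sidecar = json.loads(js.read_text())
    for field in ("fs", "t_first_sample", "labels"):
        if sidecar.get(field) is None:
            raise ConfigurationError(f"epoch sidecar missing field {field!r}")
    return EpochedDataset(
        data=data,
        labels=np.asarray(sidecar["labels"]),
        fs=float(sidecar["fs"]),
        t_first_sample=float(sidecar["t_first_sample"]),
        participant_id=sidecar.get("participant_id", "p0"),
        rt=np.asarray(sidecar["rt"], float) if sidecar.get("rt") is not None else None,
        category_names=sidecar.get("category_names"),
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(outdir: str | Path, config: dict, seed: int, extra: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def curves_to_frame(curves: dict[str, DecodingCurve]) -> pd.DataFrame:
    """Long-format (method, participant, window_ms, accuracy)."""
    rows = []
    for method, curve in curves.items():
        for p in range(curve.accuracy.shape[0]):
            for wi, wc in enumerate(curve.window_centers):
                rows.append(
                    {
                        "method": method,
                        "participant": p,
                        "window_ms": float(wc),
                        "accuracy": float(curve.accuracy[p, wi]),
                    }
                )
    return pd.DataFrame(rows)


def bayes_to_frame(series: BayesSeries, method: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": method,
            "window_ms": series.window_centers,
            "bf": series.bf,
            "evidence": series.evidence,
        }
    )


def behavior_to_frame(series: BehaviorCorrSeries, method: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": method,
            "window_ms": series.window_centers,
            "rho": series.rho,
            "p": series.p if series.p is not None else np.nan,
            "q": series.q if series.q is not None else np.nan,
            "significant": (
                series.significant if series.significant is not None else False
            ),
        }
    )


def curve_params_to_frame(params: CurveParams, method: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": method,
            "participant": np.arange(params.max_acc.size),
            "max_acc": params.max_acc,
            "mean_acc": params.mean_acc,
            "t_max_ms": params.t_max,
            "t_onset_ms": params.t_onset,
        }
    )
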