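"""Leakage-free PCA stages of the decoding pipeline.

Three places in the pipeline use PCA, always fit on the training trials of
the current cross-validation fold and applied to training and test trials
with the same parameters (means and loadings):

* *equalization* — multi-valued features (n x e*f) are reduced to one
  value per electrode (n x e) so they compare fairly against single-valued
  features;
* *scalarization* — each n x e feature is projected to a single column
  for the feature-selection scorers (never used for decoding itself);
* *combination* — the five selected n x e features are concatenated to
  n x 5e and reduced back to n x e so the combined space has the same
  dimensionality as any individual feature.

Centering only, no variance scaling. The component sign convention (the
largest-magnitude loading entry is positive) makes runs reproducible
across platforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import ConfigurationError

__all__ = [
    "PcaModel",
    "fit_pca",
    "apply_pca",
    "equalize_multivalued",
    "scalarize_for_selection",
    "combine_selected",
]


@dataclass
class PcaModel:
    """Training-fold column means plus ordered orthonormal loadings."""

    column_means: np.ndarray  # (p,)
    loadings: np.ndarray  # (k, p), rows are unit vectors (zero rows if padded)
    explained_variance: np.ndarray  # (k,), non-increasing
    k: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "column_means": self.column_means.tolist(),
                "loadings": self.loadings.tolist(),
                "explained_variance": self.explained_variance.tolist(),
                "k": self.k,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PcaModel":
        d = json.loads(s)
        return cls(
            column_means=np.asarray(d["column_means"], float),
            loadings=np.asarray(d["loadings"], float),
            explained_variance=np.asarray(d["explained_variance"], float),
            k=int(d["k"]),
        )


def fit_pca(train_matrix: np.ndarray, k: int, allow_rank_deficit: bool = False) -> PcaModel:
    """Fit PCA on a training matrix, retaining ``k`` components.

    Components are ordered by explained variance with a deterministic sign
    convention. With ``allow_rank_deficit`` the model keeps the available
    rank and zero-pads loadings to ``k`` (with a warning) so downstream
    shapes hold; otherwise ``k`` beyond ``min(n-1, p)`` is a contract
    error.
    """
    X = np.asarray(train_matrix, float)
    if X.ndim != 2:
        raise ConfigurationError("fit_pca expects a 2-D matrix")
    n, p = X.shape
    if not np.isfinite(X).all():
        raise ConfigurationError("fit_pca input contains non-finite values")
    kmax = min(n - 1, p)
    if k > kmax and not allow_rank_deficit:
        raise ConfigurationError(f"k={k} exceeds min(n_train-1, p)={kmax}")
    means = X.mean(axis=0)
    Xc = X - means
    if not Xc.any():
        raise ConfigurationError("fit_pca: training matrix has zero variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(n, p) * np.finfo(float).eps
    rank = int(np.count_nonzero(s > tol))
    keep = min(k, rank)
    if keep < k:
        warnings.warn(
            f"training rank {rank} < requested k={k}; retaining {keep} "
            "components and zero-padding",
            stacklevel=2,
        )
    loadings = Vt[:keep]
    ev = s[:keep] ** 2 / max(n - 1, 1)
    # sign convention: largest-magnitude entry of each loading positive
    flip = np.sign(loadings[np.arange(keep), np.argmax(np.abs(loadings), axis=1)])
    loadings = loadings * flip[:, None]
    if keep < k:
        loadings = np.vstack([loadings, np.zeros((k - keep, p))])
        ev = np.concatenate([ev, np.zeros(k - keep)])
    return PcaModel(column_means=means, loadings=loadings, explained_variance=ev, k=k)


def apply_pca(model: PcaModel, matrix: np.ndarray) -> np.ndarray:
    """Project rows onto the model's loadings after centering by its means."""
    X = np.asarray(matrix, float)
    if X.shape[1] != model.column_means.shape[0]:
        raise ConfigurationError(
            f"column mismatch: matrix has {X.shape[1]} columns, model expects "
            f"{model.column_means.shape[0]}"
        )
    return (X - model.column_means) @ model.loadings.T


def equalize_multivalued(
    values: np.ndarray, n_electrodes: int, train_idx: np.ndarray
) -> np.ndarray:
    """Stage-3 reduction: n x (e*f) -> n x e via training-fold PCA.

    Single-valued input (f = 1) passes through unchanged. The PCA is fit
    on the training rows over all e*f columns and applied to every row.
    """
    X = np.asarray(values, float)
    if X.shape[1] == n_electrodes:
        return X
    model = fit_pca(X[train_idx], k=n_electrodes, allow_rank_deficit=True)
    return apply_pca(model, X)


def scalarize_for_selection(values: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Stage-4 reduction: n x e -> n x 1 via training-fold PCA (k = 1)."""
    X = np.asarray(values, float)
    model = fit_pca(X[train_idx], k=1, allow_rank_deficit=True)
    return apply_pca(model, X)


def combine_selected(
    selected: list[np.ndarray], n_electrodes: int, train_idx: np.ndarray
) -> np.ndarray:
    """Stages 6-7: concatenate k selected n x e features, reduce to n x e.

    The concatenated matrix is n x (k*e); a training-fold PCA retains e
    components so the combined space is directly comparable to any
    individual feature.
    """
    shapes = {m.shape for m in selected}
    ns = {m.shape[0] for m in selected}
    if len(ns) != 1 or any(m.shape[1] != n_electrodes for m in selected):
        raise ConfigurationError(f"selected features have mismatched shapes: {shapes}")
    concat = np.concatenate(selected, axis=1)
    model = fit_pca(concat[train_idx], k=n_electrodes, allow_rank_deficit=True)
    return apply_pca(model, concat)
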