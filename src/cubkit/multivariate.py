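"""PCA over 59-dimensional RSCU vectors."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .genetics import CubkitError
from .rscu import RscuProfile


@dataclass(frozen=True)
class PcaResult:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # (n_profiles, n_axes)
    explained_variance_pct: np.ndarray
    loadings: np.ndarray  # (n_axes, 59)
    n_axes: int


def profiles_to_matrix(profiles: list[RscuProfile]) -> np.ndarray:
    code = profiles[0].code
    mat = np.array([p.as_vector(code.sense_codons) for p in profiles], dtype=float)
    if np.isnan(mat).any():
        raise CubkitError("PCA needs complete 59-codon profiles (no unobserved families)")
    return mat


def pca_rscu(
    profiles: list[RscuProfile],
    n_axes: int = 2,
    ids: list[str] | None = None,
) -> PcaResult:
    """Mean-centred covariance PCA; axis signs fixed so each axis's
    largest-magnitude loading is positive. Zero-variance input yields
    all-zero coordinates with a warning rather than an error."""
    if len(profiles) < 2:
        raise CubkitError("PCA needs at least 2 profiles")
    mat = profiles_to_matrix(profiles)
    ids = tuple(ids) if ids is not None else tuple(f"p{i}" for i in range(len(mat)))
    n_axes = min(n_axes, len(mat) - 1, mat.shape[1])

    centred = mat - mat.mean(axis=0)
    if np.allclose(centred, 0.0):
        warnings.warn("zero total variance; returning all-zero coordinates")
        return PcaResult(
            ids=ids,
            coordinates=np.zeros((len(mat), n_axes)),
            explained_variance_pct=np.zeros(n_axes),
            loadings=np.zeros((n_axes, mat.shape[1])),
            n_axes=n_axes,
        )

    model = PCA(n_components=n_axes)
    coords = model.fit_transform(mat)
    loadings = model.components_
    # deterministic sign: largest-|loading| entry of each axis made positive
    for ax in range(n_axes):
        pivot = np.argmax(np.abs(loadings[ax]))
        if loadings[ax, pivot] < 0:
            loadings[ax] *= -1.0
            coords[:, ax] *= -1.0
    return PcaResult(
        ids=ids,
        coordinates=coords,
        explained_variance_pct=model.explained_variance_ratio_ * 100.0,
        loadings=loadings,
        n_axes=n_axes,
    )
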