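"""PCA noise reduction for pair feature vectors.

Concatenated pair descriptors carry correlated coordinates (singular-vector
entries scaled by sqrt(singular value)); a centered principal component
analysis removes low-variance directions before classification.  Features
share a common scale, so the data are centered but not per-feature rescaled.
The retained dimension defaults to the smallest k explaining 95% of the
variance, overridable by an explicit component count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

__all__ = ["PCAModel", "PCAConfig", "fit_pca", "apply_pca"]


@dataclass(frozen=True)
class PCAConfig:
    """Settings forwarded to :func:`fit_pca` by the pipeline."""

    variance_target: float = 0.95
    n_components: Optional[int] = None


@dataclass(frozen=True)
class PCAModel:
    """Fitted centered PCA: projection onto the top-k principal axes."""

    mean: np.ndarray                      # (D,)
    components: np.ndarray                # (k, D), orthonormal rows
    explained_variance: np.ndarray        # (k,) eigenvalues, descending
    explained_variance_ratio: np.ndarray  # (k,) in (0, 1], descending

    @property
    def k(self) -> int:
        return int(self.components.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.components.shape[1])


def fit_pca(
    X: np.ndarray,
    variance_target: float = 0.95,
    n_components: Optional[int] = None,
) -> PCAModel:
    """Fit centered PCA on an n x D feature matrix.

    When ``n_components`` is given it is used directly; otherwise the
    smallest k whose cumulative explained-variance ratio reaches
    ``variance_target`` is retained.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got ndim={X.ndim}")
    n, D = X.shape
    if n < 2:
        raise ValueError(f"PCA needs at least 2 rows, got {n}")
    if not (0 < variance_target <= 1):
        raise ValueError(f"variance_target must be in (0, 1], got {variance_target}")
    if np.allclose(X, X[0], rtol=0.0, atol=1e-12):
        raise ValueError("all rows identical: zero-variance input")
    max_k = min(n - 1, D)
    if n_components is not None:
        if not (1 <= n_components <= max_k):
            raise ValueError(
                f"n_components={n_components} must be in [1, min(n-1, D)={max_k}]"
            )

    sk = _SkPCA(n_components=max_k, svd_solver="full")
    sk.fit(X)
    if n_components is not None:
        k = n_components
    else:
        cumulative = np.cumsum(sk.explained_variance_ratio_)
        k = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
        k = min(k, max_k)
    return PCAModel(
        mean=sk.mean_.copy(),
        components=sk.components_[:k].copy(),
        explained_variance=sk.explained_variance_[:k].copy(),
        explained_variance_ratio=sk.explained_variance_ratio_[:k].copy(),
    )


def apply_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project an m x D matrix onto the model's principal axes: (X - mean) W^T."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, "
            f"got {X.shape[1]}"
        )
    return (X - model.mean) @ model.components.T
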