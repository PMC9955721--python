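"""Principal component analysis of training features.

Implemented directly as an eigendecomposition of the training covariance
(unbiased, n-1 denominator) so that every quantity — mean, components,
eigenvalues — is auditable. Component signs are canonicalized by making
each component's largest-magnitude coordinate positive, which makes fits
reproducible across platforms. The model is always fitted on training
rows only; test rows are projected with the training mean and basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import PSDFeatureMatrix

_ORTHO_TOL = 1e-8


@dataclass
class PCAModel:
    mean_vector: np.ndarray          # (d,)
    components: np.ndarray           # (k, d), rows orthonormal
    eigenvalues: np.ndarray          # (d,), descending
    n_components_retained: int
    explained_variance_fraction: float

    def __post_init__(self) -> None:
        g = self.components @ self.components.T
        if not np.allclose(g, np.eye(len(self.components)), atol=1e-6):
            raise ValueError("components are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > _ORTHO_TOL):
            raise ValueError("eigenvalues must be sorted descending")
        if not 0 < self.explained_variance_fraction <= 1 + 1e-12:
            raise ValueError("explained fraction must lie in (0, 1]")


def _values_of(m: PSDFeatureMatrix | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, PSDFeatureMatrix) else np.asarray(m, float)


def canonical_sign(components: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-|coordinate| entry is positive."""
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_pca(
    train: PSDFeatureMatrix | np.ndarray, retain: float | int = 0.95
) -> PCAModel:
    """Fit PCA on training rows.

    ``retain``: a float f in (0, 1] keeps the smallest number of leading
    components whose cumulative eigenvalue fraction reaches f; an int k
    keeps exactly k components (k must not exceed the data rank).
    """
    x = _values_of(train)
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 rows to fit PCA")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are components

    total = float(evals.sum())
    if total <= 0:
        raise ValueError("zero-variance training data")
    rank = int(np.sum(evals > max(evals[0], 1.0) * 1e-12))

    if isinstance(retain, (bool,)):
        raise TypeError("retain must be a float fraction or an int count")
    if isinstance(retain, (int, np.integer)):
        k = int(retain)
        if k < 1:
            raise ValueError("retain count must be >= 1")
        if k > rank:
            raise ValueError(
                f"requested {k} components but the data rank is {rank}"
            )
    else:
        f = float(retain)
        if not 0 < f <= 1:
            raise ValueError("retain fraction must be in (0, 1]")
        cum = np.cumsum(evals) / total
        k = int(np.searchsorted(cum, f - 1e-12) + 1)
        k = min(k, rank if rank > 0 else 1)

    return PCAModel(
        mean_vector=mean,
        components=canonical_sign(evecs[:k]),
        eigenvalues=evals,
        n_components_retained=k,
        explained_variance_fraction=float(evals[:k].sum() / total),
    )


def transform(model: PCAModel, m: PSDFeatureMatrix | np.ndarray) -> np.ndarray:
    """Project rows onto the retained components; returns (n, k) scores."""
    x = _values_of(m)
    if x.shape[1] != model.mean_vector.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has {x.shape[1]} columns, model "
            f"expects {model.mean_vector.shape[0]}"
        )
    return (x - model.mean_vector) @ model.components.T


def inverse_transform(model: PCAModel, z: np.ndarray) -> np.ndarray:
    """Map scores back to the original feature space."""
    z = np.asarray(z, float)
    if z.shape[1] != model.n_components_retained:
        raise ValueError("score dimensionality does not match the model")
    return z @ model.components + model.mean_vector
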