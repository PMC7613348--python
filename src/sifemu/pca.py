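"""Principal component compression of spectra.

Both sides of the emulator use the same machinery: spectra are mean-centered
(no variance scaling), the leading ``p`` eigenvectors ``U`` of the unbiased
sample covariance are retained, scores are ``W = (X - mean) U^T`` and spectra
are rebuilt as ``X^ = W U + mean``. Eigenvector signs are fixed so the
largest-magnitude entry of each component is positive (first such entry on
ties), which makes fits bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import BandGrid, SpectralMatrix
from .errors import ArgumentError, ShapeError


@dataclass
class PCAModel:
    mean: np.ndarray          # [B]
    U: np.ndarray             # [p, B], rows orthonormal, descending eigenvalue
    eigenvalues: np.ndarray   # [p], non-increasing, >= 0
    total_variance: float     # trace of the sample covariance
    grid: BandGrid

    @property
    def p(self) -> int:
        return self.U.shape[0]

    @property
    def n_bands(self) -> int:
        return self.U.shape[1]


@dataclass
class ScoreMatrix:
    values: np.ndarray        # [n, p]
    model: PCAModel

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.model.p:
            raise ShapeError("score column count does not match model components")


def _fix_signs(U: np.ndarray) -> np.ndarray:
    # flip each row so its largest-|entry| (first on ties) is positive
    idx = np.argmax(np.abs(U), axis=1)
    signs = np.sign(U[np.arange(U.shape[0]), idx])
    signs[signs == 0] = 1.0
    return U * signs[:, None]


def fit_pca(X: SpectralMatrix, p: int) -> PCAModel:
    """Fit a ``p``-component PCA to the rows of ``X``.

    Zero-variance data yield a valid model with all-zero eigenvalues.
    """
    values = X.values
    n, B = values.shape
    if n < 2:
        raise ArgumentError("PCA needs at least 2 samples")
    if not (1 <= p <= min(n - 1, B)):
        raise ArgumentError(f"p={p} outside [1, min(n-1, B)] = [1, {min(n - 1, B)}]")
    mean = values.mean(axis=0)
    centered = values - mean
    # economy SVD: covariance eigenvalues are s^2 / (n - 1), rows of Vt are
    # the eigenvectors; cheaper and more stable than forming the covariance
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = (s ** 2) / (n - 1)
    U = _fix_signs(Vt[:p])
    total = float(centered.var(axis=0, ddof=1).sum()) if n > 1 else 0.0
    return PCAModel(mean=mean, U=np.ascontiguousarray(U),
                    eigenvalues=eigenvalues[:p].copy(),
                    total_variance=total, grid=X.grid)


def project(model: PCAModel, X: SpectralMatrix) -> ScoreMatrix:
    """Scores ``W = (X - mean) U^T``."""
    if X.values.shape[1] != model.n_bands:
        raise ShapeError(
            f"spectra have {X.values.shape[1]} bands, model expects {model.n_bands}"
        )
    return ScoreMatrix((X.values - model.mean) @ model.U.T, model)


def reconstruct(model: PCAModel, W: ScoreMatrix | np.ndarray) -> SpectralMatrix:
    """Spectra ``X^ = W U + mean`` on the model's grid."""
    values = W.values if isinstance(W, ScoreMatrix) else np.atleast_2d(np.asarray(W, float))
    if values.shape[1] != model.p:
        raise ShapeError(
            f"scores have {values.shape[1]} components, model retains {model.p}"
        )
    return SpectralMatrix(values @ model.U + model.mean, model.grid)


def explained_variance(model: PCAModel) -> np.ndarray:
    """Fraction of total variance captured by each retained component."""
    if model.total_variance <= 0:
        return np.zeros(model.p)
    return model.eigenvalues / model.total_variance
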