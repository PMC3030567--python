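"""Quasi-harmonic analysis: covariance eigenmodes and whitening.

QHA is PCA of the mass-unweighted positional-deviation covariance
C = X^T X / T.  Its eigenvectors E (harmonic modes) and eigenvalues
Lambda (mode variances, A^2) define the whitening basis
B = Lambda^(-1/2) E^T, whose projections H = X B^T have identity
covariance -- all second-order correlations removed.  QHA serves both
as a comparison baseline and as the dimensionality-reducing front end
of the anharmonic decomposition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensembles import DeviationMatrix

__all__ = [
    "HarmonicBasis",
    "covariance_matrix",
    "harmonic_basis",
    "whiten_project",
    "back_project",
]


@dataclass
class HarmonicBasis:
    """Eigenpairs of the deviation covariance plus the whitening map.

    eigenvalues : (m,) descending, A^2
    eigenvectors : (3n, m) column-orthonormal
    whitening : B = Lambda^(-1/2) E^T, (m, 3n)
    variance_fraction : cumulative fraction of total variance retained
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    whitening: np.ndarray
    retained_m: int
    variance_fraction: float
    total_variance: float

    @property
    def m(self) -> int:
        return self.retained_m


def _as_matrix(dev) -> np.ndarray:
    return dev.X if isinstance(dev, DeviationMatrix) else np.asarray(dev, float)


def covariance_matrix(dev: DeviationMatrix | np.ndarray) -> np.ndarray:
    """Population covariance C = X^T X / T of mean-removed deviations."""
    X = _as_matrix(dev)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    C = X.T @ X / X.shape[0]
    return 0.5 * (C + C.T)


def harmonic_basis(
    C: np.ndarray,
    mode_count: int | None = None,
    variance_target: float | None = None,
) -> HarmonicBasis:
    """Eigen-decompose C and build the whitening basis.

    Exactly one of ``mode_count`` / ``variance_target`` selects the
    retained dimensionality; with a variance target the smallest m whose
    cumulative variance fraction reaches the target is kept.  Eigenvalues
    below 1e-10 of the largest are dropped before whitening to avoid
    dividing by numerical zeros.  Eigenvector signs are fixed so the
    largest-magnitude component of each mode is positive.
    """
    if (mode_count is None) == (variance_target is None):
        raise ValueError("give exactly one of mode_count / variance_target")
    C = np.asarray(C, dtype=float)
    evals, evecs = np.linalg.eigh(0.5 * (C + C.T))
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]

    total = float(evals.sum())
    rank = int(np.sum(evals > 1e-10 * max(evals[0], 1e-300)))
    if mode_count is not None:
        if mode_count < 1 or mode_count > rank:
            raise ValueError(f"mode_count must be in [1, rank={rank}]")
        m = mode_count
    else:
        if not 0 < variance_target <= 1:
            raise ValueError("variance_target must lie in (0, 1]")
        cum = np.cumsum(evals) / total
        m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        m = min(m, rank)

    evals, evecs = evals[:m], evecs[:, :m]
    # reproducible sign: largest-magnitude component positive
    flips = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(m)])
    evecs = evecs * flips
    B = evecs.T / np.sqrt(evals)[:, None]
    return HarmonicBasis(
        eigenvalues=evals,
        eigenvectors=evecs,
        whitening=B,
        retained_m=m,
        variance_fraction=float(evals.sum() / total) if total > 0 else 1.0,
        total_variance=total,
    )


def whiten_project(dev: DeviationMatrix | np.ndarray, basis: HarmonicBasis) -> np.ndarray:
    """Whitened projections H = X B^T (frames x m, identity covariance)."""
    X = _as_matrix(dev)
    if X.shape[1] != basis.whitening.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} coords, "
            f"basis expects {basis.whitening.shape[1]}"
        )
    return X @ basis.whitening.T


def back_project(vec: np.ndarray, basis: HarmonicBasis) -> np.ndarray:
    """Map mode-space coordinates back to 3n space: E Lambda^(1/2) v."""
    v = np.asarray(vec, dtype=float)
    if v.shape[-1] != basis.retained_m:
        raise ValueError("dimension mismatch with retained modes")
    return (basis.eigenvectors * np.sqrt(basis.eigenvalues)) @ v
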