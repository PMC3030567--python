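"""Quasi-anharmonic decomposition: cumulant matrices, joint
diagonalization by Jacobi rotations, and the anharmonic basis.

Whitening leaves a rotational degeneracy: any orthogonal rotation of
whitened projections z also has identity covariance.  The rotation V is
fixed by fourth-order statistics -- the set of cumulant matrices
Q(i,j) with entries cum(z_i, z_j, z_k, z_l) is jointly diagonalized by
Givens rotation sweeps (the JADE strategy).  The resulting mixing
matrix A = E Lambda^(1/2) V holds the (generally non-orthogonal)
anharmonic modes of motion in coordinate space; the demixing map
Gamma = V^T B recovers unit-variance anharmonic sources s = Gamma x.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensembles import DeviationMatrix
from .qha import HarmonicBasis, whiten_project

__all__ = [
    "CumulantMatrixSet",
    "AnharmonicBasis",
    "CouplingMatrix",
    "fourth_cross_cumulant",
    "cumulant_matrix_set",
    "joint_diagonalize",
    "JadeResult",
    "anharmonic_basis",
    "project_anharmonic",
    "coupling_matrix",
    "commonly_activated_atoms",
    "qaa_decompose",
]

#: above this whitened dimensionality the full m(m+1)/2 cumulant-matrix
#: set (memory ~ m^4) is replaced by its m most significant eigenmatrices
TRUNCATE_ABOVE = 40


def fourth_cross_cumulant(Z: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Sample fourth-order cross-cumulant of whitened columns.

    cum(z_i,z_j,z_k,z_l) = E[z_i z_j z_k z_l] - E[z_i z_j] E[z_k z_l]
    - E[z_i z_k] E[z_j z_l] - E[z_i z_l] E[z_j z_k], with expectations
    replaced by sample means.  Vanishes for Gaussian data; this is the
    naive oracle the fast matrix construction is tested against.
    """
    Z = np.asarray(Z, dtype=float)
    m = Z.shape[1]
    for idx in (i, j, k, l):
        if not 0 <= idx < m:
            raise IndexError(f"index {idx} out of range (m={m})")
    zi, zj, zk, zl = Z[:, i], Z[:, j], Z[:, k], Z[:, l]
    e = lambda a: float(np.mean(a))
    return (
        e(zi * zj * zk * zl)
        - e(zi * zj) * e(zk * zl)
        - e(zi * zk) * e(zj * zl)
        - e(zi * zl) * e(zj * zk)
    )


@dataclass
class CumulantMatrixSet:
    """Parallel set of m x m cumulant matrices Q(i,j), i <= j.

    ``weights`` carry the tensor multiplicity (2 for i < j pairs, since
    Q(i,j) = Q(j,i)); eigenmatrix-truncated sets carry unit weights.
    """

    matrices: np.ndarray  # (n_matrices, m, m)
    pairs: list[tuple[int, int]]
    weights: np.ndarray
    sample_count: int
    truncated: bool = False

    @property
    def m(self) -> int:
        return self.matrices.shape[1]


def cumulant_matrix_set(Z: np.ndarray, truncate: bool = False) -> CumulantMatrixSet:
    """All fourth-order cumulant matrices of whitened data.

    [Q(i,j)]_{k,l} = cum(z_i, z_j, z_k, z_l) with sample moments, for
    i <= j (the full set has m(m+1)/2 matrices).  With ``truncate`` the
    set is replaced by the m most significant eigenmatrices of the
    stacked m^2 x m^2 cumulant, scaled by their eigenvalues.
    """
    Z = np.asarray(Z, dtype=float)
    T, m = Z.shape
    R = Z.T @ Z / T
    dev = np.abs(R - np.eye(m)).max()
    mean_dev = np.abs(Z.mean(axis=0)).max()
    if dev > 1e-3 or mean_dev > 1e-3:
        raise ValueError(
            f"input is not whitened: max |cov - I| = {dev:.2e}, "
            f"max |mean| = {mean_dev:.2e}"
        )

    mats = []
    pairs = []
    wts = []
    for i in range(m):
        for j in range(i, m):
            w = Z[:, i] * Z[:, j]
            M = (Z.T * w) @ Z / T
            Q = (
                M
                - R * R[i, j]
                - np.outer(R[:, i], R[:, j])
                - np.outer(R[:, j], R[:, i])
            )
            mats.append(0.5 * (Q + Q.T))
            pairs.append((i, j))
            wts.append(1.0 if i == j else 2.0)
    matrices = np.array(mats)
    weights = np.array(wts)

    if truncate:
        # stack into the symmetric m^2 x m^2 cumulant and keep the m
        # leading eigenmatrices (by |eigenvalue|), eigenvalue-scaled
        C4 = np.zeros((m * m, m * m))
        for (i, j), Q in zip(pairs, matrices):
            C4[i * m + j] = Q.ravel()
            C4[j * m + i] = Q.ravel()
        evals, evecs = np.linalg.eigh(0.5 * (C4 + C4.T))
        top = np.argsort(np.abs(evals))[::-1][:m]
        mats = []
        for r in top:
            Mr = evals[r] * evecs[:, r].reshape(m, m)
            mats.append(0.5 * (Mr + Mr.T))
        matrices = np.array(mats)
        pairs = [(-1, -1)] * m
        weights = np.ones(m)

    return CumulantMatrixSet(
        matrices=matrices,
        pairs=pairs,
        weights=weights,
        sample_count=T,
        truncated=truncate,
    )


@dataclass
class JadeResult:
    rotation: np.ndarray
    residual: float
    sweeps: int
    converged: bool
    residual_history: list = field(default_factory=list)


def _off_diag_residual(M: np.ndarray, weights: np.ndarray) -> float:
    off = M - M * np.eye(M.shape[1])[None]
    return float(np.einsum("r,rkl->", weights, off**2))


def joint_diagonalize(
    cm: CumulantMatrixSet,
    theta_min: float | None = None,
    max_sweeps: int = 200,
) -> JadeResult:
    """Orthogonal V minimizing summed squared off-diagonals of V^T Q V.

    Jacobi sweeps over index pairs (p, q); each Givens angle has the
    closed-form optimum of the weighted joint-diagonality objective.
    Sweeping stops when every rotation sine in a sweep falls below
    ``theta_min`` or after ``max_sweeps``.  The default threshold
    1e-2 / sqrt(T) is the statistical resolution of sample cumulants:
    smaller rotations only chase sampling noise.
    """
    M = cm.matrices.copy()
    w = cm.weights
    n_mat, m, _ = M.shape
    if n_mat < 1:
        raise ValueError("need at least one cumulant matrix")
    if theta_min is None:
        theta_min = 1e-2 / np.sqrt(max(cm.sample_count, 1))

    # Gaussian data leaves the rotation unidentifiable (all cumulants ~ 0)
    noise_scale = 5.0 * np.sqrt(24.0 / max(cm.sample_count, 1))
    if np.abs(M).max() < noise_scale:
        warnings.warn(
            "all fourth-order cumulants are at the Gaussian noise floor; "
            "the anharmonic rotation is unidentifiable",
            RuntimeWarning,
        )

    V = np.eye(m)
    history = [_off_diag_residual(M, w)]
    converged = False
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        rotated = False
        for p in range(m - 1):
            for q in range(p + 1, m):
                g1 = M[:, p, p] - M[:, q, q]
                g2 = M[:, p, q] + M[:, q, p]
                g11 = float(np.dot(w, g1 * g1))
                g22 = float(np.dot(w, g2 * g2))
                g12 = float(np.dot(w, g1 * g2))
                ton = g11 - g22
                toff = 2.0 * g12
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) <= theta_min:
                    continue
                rotated = True
                # M <- G^T M G with G the Givens rotation in (p, q)
                Mp = M[:, p, :].copy()
                Mq = M[:, q, :].copy()
                M[:, p, :] = c * Mp + s * Mq
                M[:, q, :] = -s * Mp + c * Mq
                Mp = M[:, :, p].copy()
                Mq = M[:, :, q].copy()
                M[:, :, p] = c * Mp + s * Mq
                M[:, :, q] = -s * Mp + c * Mq
                Vp = V[:, p].copy()
                V[:, p] = c * Vp + s * V[:, q]
                V[:, q] = -s * Vp + c * V[:, q]
        history.append(_off_diag_residual(M, w))
        if not rotated:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"joint diagonalization did not converge in {max_sweeps} sweeps; "
            "returning best rotation found",
            RuntimeWarning,
        )
    return JadeResult(
        rotation=V,
        residual=history[-1],
        sweeps=sweeps,
        converged=converged,
        residual_history=history,
    )


@dataclass
class AnharmonicBasis:
    """Anharmonic modes (mixing A), demixing Gamma and their rotation V.

    Columns a_i of A (3n x m, A units) are the anharmonic modes of
    motion, sorted by decreasing amplitude ||a_i||; sources s = Gamma x
    have identity covariance.  A need not be column-orthogonal.
    """

    rotation: np.ndarray      # V, m x m orthogonal
    demixing: np.ndarray      # Gamma = V^T B, m x 3n
    mixing: np.ndarray        # A = E Lambda^(1/2) V, 3n x m
    amplitudes: np.ndarray    # ||a_i||, descending
    harmonic: HarmonicBasis
    off_diag_residual: float | None = None

    @property
    def m(self) -> int:
        return self.mixing.shape[1]


def anharmonic_basis(
    dev: DeviationMatrix | np.ndarray,
    hb: HarmonicBasis,
    V: np.ndarray,
    off_diag_residual: float | None = None,
) -> AnharmonicBasis:
    """Assemble mixing/demixing matrices from the whitening basis and V.

    Gamma = V^T B and A = E Lambda^(1/2) V, so Gamma A = I_m; columns
    are re-ordered by decreasing amplitude ||a_i|| (stable, original
    index breaks ties) and sign-fixed so each mode's largest-magnitude
    entry is positive.
    """
    V = np.asarray(V, dtype=float)
    m = hb.retained_m
    if V.shape != (m, m):
        raise ValueError(f"V must be {m} x {m}")
    if np.abs(V.T @ V - np.eye(m)).max() > 1e-8:
        raise ValueError("V must be orthogonal")

    A = (hb.eigenvectors * np.sqrt(hb.eigenvalues)) @ V
    gamma = V.T @ hb.whitening
    amps = np.linalg.norm(A, axis=0)
    order = np.argsort(-amps, kind="stable")
    A, gamma, V_ord = A[:, order], gamma[order], V[:, order]
    amps = amps[order]
    flips = np.sign(A[np.abs(A).argmax(axis=0), np.arange(m)])
    flips[flips == 0] = 1.0
    A = A * flips
    gamma = gamma * flips[:, None]
    V_ord = V_ord * flips
    return AnharmonicBasis(
        rotation=V_ord,
        demixing=gamma,
        mixing=A,
        amplitudes=amps,
        harmonic=hb,
        off_diag_residual=off_diag_residual,
    )


def project_anharmonic(
    dev: DeviationMatrix | np.ndarray,
    ab: AnharmonicBasis,
    k: int | None = None,
) -> np.ndarray:
    """First k columns of the source projections S = X Gamma^T."""
    X = dev.X if isinstance(dev, DeviationMatrix) else np.asarray(dev, float)
    if k is None:
        k = ab.m
    if not 1 <= k <= ab.m:
        raise ValueError(f"k must be in [1, {ab.m}]")
    return X @ ab.demixing[:k].T


@dataclass
class CouplingMatrix:
    """Absolute-cosine coupling between anharmonic modes, in [0, 1]."""

    c: np.ndarray

    def __post_init__(self):
        if np.abs(self.c - self.c.T).max() > 1e-10:
            raise ValueError("coupling matrix must be symmetric")


def coupling_matrix(ab: AnharmonicBasis) -> CouplingMatrix:
    """Mode-coupling strengths c_ij = |a_i . a_j| / (||a_i|| ||a_j||).

    Orthogonal modes give 0, parallel modes 1; because the anharmonic
    basis is non-orthogonal the off-diagonals are generally nonzero and
    measure how strongly one mode's activation implicates another.
    """
    A = ab.mixing
    if A.shape[1] < 2:
        raise ValueError("need at least 2 modes")
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm mixing column")
    c = np.abs(A.T @ A) / np.outer(norms, norms)
    np.fill_diagonal(c, 1.0)
    return CouplingMatrix(c=0.5 * (c + c.T))


def commonly_activated_atoms(
    ab: AnharmonicBasis, i: int, j: int, quantile: float = 0.9
) -> np.ndarray:
    """Atoms strongly displaced by both modes i and j.

    Per-atom displacement norms are computed within each mixing column;
    atoms above the ``quantile`` threshold in both modes are reported.
    """
    n = ab.mixing.shape[0] // 3
    norms_i = np.linalg.norm(ab.mixing[:, i].reshape(n, 3), axis=1)
    norms_j = np.linalg.norm(ab.mixing[:, j].reshape(n, 3), axis=1)
    ti = np.quantile(norms_i, quantile)
    tj = np.quantile(norms_j, quantile)
    return np.where((norms_i >= ti) & (norms_j >= tj))[0]


def qaa_decompose(
    dev: DeviationMatrix | np.ndarray,
    mode_count: int | None = None,
    variance_target: float | None = 0.9,
    max_modes: int | None = None,
    truncate: bool | None = None,
    theta_min: float | None = None,
    max_sweeps: int = 200,
) -> AnharmonicBasis:
    """Full pipeline: covariance -> whitening -> JADE -> anharmonic basis.

    ``max_modes`` caps the retained whitened dimensionality after the
    variance target is applied (the usual protein protocol projects onto
    a few tens of quasi-harmonic dimensions first).  ``truncate=None``
    picks the eigenmatrix-truncated cumulant set automatically above 40
    whitened dimensions.
    """
    from .qha import covariance_matrix, harmonic_basis

    C = covariance_matrix(dev)
    if mode_count is not None:
        hb = harmonic_basis(C, mode_count=mode_count)
    else:
        hb = harmonic_basis(C, variance_target=variance_target)
        if max_modes is not None and hb.retained_m > max_modes:
            hb = harmonic_basis(C, mode_count=max_modes)
    Z = whiten_project(dev, hb)
    if truncate is None:
        truncate = hb.retained_m > TRUNCATE_ABOVE
    cm = cumulant_matrix_set(Z, truncate=truncate)
    res = joint_diagonalize(cm, theta_min=theta_min, max_sweeps=max_sweeps)
    return anharmonic_basis(dev, hb, res.rotation, off_diag_residual=res.residual)
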