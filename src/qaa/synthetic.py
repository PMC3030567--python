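"""Synthetic ensembles with known ground truth.

Three generator families make every stage of the pipeline testable
without MD data: (a) linearly mixed non-Gaussian sources with a known
non-orthogonal mixing matrix (blind-source-separation benchmark),
(b) toy polymer ensembles with planted multi-well sub-states, planted
per-frame energies, and optional Gaussian collective modes emulating
harmonic protein motions, and (c) an umbrella-window emulator sweeping
a central dihedral reaction coordinate from trans to cis.  The Amari
index quantifies recovery of a planted mixing matrix up to
permutation, scale and sign.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationTrack
from .ensembles import ConformationalEnsemble, _default_meta

__all__ = [
    "SourceSpec",
    "SyntheticTruth",
    "Well",
    "make_ica_dataset",
    "amari_index",
    "make_toy_ensemble",
    "make_reaction_pathway",
    "helix_backbone",
    "nested_substates",
    "anharmonic_energy_wells",
]


@dataclass(frozen=True)
class SourceSpec:
    """One family of unit-variance sources with known analytic kurtosis.

    kinds: gaussian (kurtosis 3), laplace (6), uniform (1.8), and
    bimodal(offset, noise_sd) -- an equal mixture of N(+-offset,
    noise_sd^2), standardized; its kurtosis follows from the planted
    mixture moments.
    """

    kind: str
    count: int = 1
    offset: float = 1.0
    noise_sd: float = 0.1

    def sample(self, T: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "gaussian":
            s = rng.standard_normal((T, self.count))
        elif self.kind == "laplace":
            s = rng.laplace(size=(T, self.count)) / np.sqrt(2.0)
        elif self.kind == "uniform":
            s = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(T, self.count))
        elif self.kind == "bimodal":
            signs = rng.choice([-1.0, 1.0], size=(T, self.count))
            s = signs * self.offset + rng.normal(0, self.noise_sd, (T, self.count))
            s /= np.sqrt(self.offset**2 + self.noise_sd**2)
        else:
            raise ValueError(f"unknown source kind {self.kind!r}")
        return s

    @property
    def analytic_kurtosis(self) -> float:
        if self.kind == "gaussian":
            return 3.0
        if self.kind == "laplace":
            return 6.0
        if self.kind == "uniform":
            return 1.8
        c, n = self.offset, self.noise_sd
        var = c**2 + n**2
        m4 = c**4 + 6 * c**2 * n**2 + 3 * n**4
        return m4 / var**2


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a synthetic dataset."""

    seed: int
    mixing_true: np.ndarray | None = None
    source_labels: np.ndarray | None = None
    energy_true: np.ndarray | None = None
    window_id: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def make_ica_dataset(
    specs: list[SourceSpec],
    T: int,
    cond_max: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Linearly mixed independent sources with a known mixing matrix.

    Sources are sampled independently and standardized; a random square
    mixing matrix is redrawn until its condition number is at most
    ``cond_max`` (non-orthogonal but well-posed); data = S A^T.
    """
    if T < 1000:
        raise ValueError("T must be >= 1000")
    rng = np.random.default_rng(seed)
    if all(sp.kind == "gaussian" for sp in specs):
        warnings.warn(
            "all sources are Gaussian: the mixing matrix is unidentifiable",
            RuntimeWarning,
        )
    S = np.hstack([sp.sample(T, rng) for sp in specs])
    S = (S - S.mean(axis=0)) / S.std(axis=0)
    m = S.shape[1]
    for _ in range(1000):
        A = rng.standard_normal((m, m))
        if np.linalg.cond(A) <= cond_max:
            break
    else:
        raise RuntimeError(f"could not draw a mixing matrix with cond <= {cond_max}")
    data = S @ A.T
    return data, SyntheticTruth(seed=seed, mixing_true=A, extras={"sources": S})


def amari_index(A_true: np.ndarray, A_est: np.ndarray) -> float:
    """Permutation/scale/sign-invariant distance between mixing matrices.

    Computed from P = A_est^+ A_true; 0 means perfect recovery of every
    source direction, ~1 means unrelated bases.
    """
    A_true = np.asarray(A_true, dtype=float)
    A_est = np.asarray(A_est, dtype=float)
    if A_true.shape != A_est.shape:
        raise ValueError("mixing matrices must have the same shape")
    m = A_true.shape[1]
    if np.linalg.matrix_rank(A_est) < m or np.linalg.matrix_rank(A_true) < m:
        raise ValueError("mixing matrices must have full column rank")
    P = np.abs(np.linalg.pinv(A_est) @ A_true)
    rows = (P.sum(axis=1) / P.max(axis=1) - 1).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1).sum()
    return float((rows + cols) / (2 * m * (m - 1)))


def helix_backbone(n_atoms: int, rise: float = 1.5, twist_deg: float = 100.0,
                   radius: float = 2.3) -> np.ndarray:
    """Ideal helical bead chain; geometry is cosmetic (viewable as PDB)."""
    i = np.arange(n_atoms)
    theta = np.radians(twist_deg) * i
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * i]
    )


def _rigid_body_basis(backbone: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3n x 6) of rigid translations/rotations."""
    n = backbone.shape[0]
    centered = backbone - backbone.mean(axis=0)
    cols = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        cols.append(t.ravel())
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        cols.append(np.cross(omega, centered).ravel())
    Q, _ = np.linalg.qr(np.column_stack(cols))
    return Q


def _remove_rigid(direction: np.ndarray, rigid: np.ndarray) -> np.ndarray:
    d = direction - rigid @ (rigid.T @ direction)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("direction lies entirely in the rigid-body subspace")
    return d / norm


@dataclass(frozen=True)
class Well:
    """One planted conformational well: a displaced point on the landscape."""

    direction: np.ndarray  # (3n,), normalized internally
    magnitude: float       # A
    energy: float          # arbitrary energy level of the well
    weight: float


def make_toy_ensemble(
    n_atoms: int,
    wells: list[Well],
    noise_sd: float = 0.1,
    T: int = 2000,
    seed: int = 0,
    jitter_sd: float = 0.3,
    harmonic_modes: int = 0,
    harmonic_sd: float = 0.0,
    energy_noise_sd: float = 0.25,
) -> tuple[ConformationalEnsemble, SyntheticTruth]:
    """Toy polymer ensemble with planted multi-well sub-states.

    Each frame picks a well by weight and sits at the helix backbone
    displaced to the well's center, with 1-D Gaussian jitter along the
    well direction, optional Gaussian collective modes (random
    directions, amplitude sd ``harmonic_sd``) emulating harmonic
    protein fluctuations, and isotropic Cartesian noise.  Every planted
    direction is orthogonalised against the rigid-body subspace so
    superposition leaves the planted structure intact.  The planted
    per-frame energy is the well's level plus Gaussian noise.
    """
    if not wells:
        raise ValueError("at least one well required")
    weights = np.array([w.weight for w in wells], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("well weights must sum to 1")
    if any(w.magnitude == 0 for w in wells):
        raise ValueError("zero-magnitude well")

    rng = np.random.default_rng(seed)
    backbone = helix_backbone(n_atoms)
    rigid = _rigid_body_basis(backbone)
    dirs = np.column_stack(
        [_remove_rigid(np.asarray(w.direction, float).ravel(), rigid) for w in wells]
    )
    h_dirs = np.empty((3 * n_atoms, 0))
    if harmonic_modes:
        h_dirs = np.column_stack(
            [
                _remove_rigid(rng.standard_normal(3 * n_atoms), rigid)
                for _ in range(harmonic_modes)
            ]
        )

    which = rng.choice(len(wells), size=T, p=weights)
    disp = dirs[:, which].T * np.array([w.magnitude for w in wells])[which, None]
    disp += dirs[:, which].T * rng.normal(0, jitter_sd, T)[:, None]
    if harmonic_modes:
        disp += rng.normal(0, harmonic_sd, (T, harmonic_modes)) @ h_dirs.T
    disp += rng.normal(0, noise_sd, disp.shape)

    coords = backbone[None] + disp.reshape(T, n_atoms, 3)
    energy = np.array([w.energy for w in wells])[which]
    energy = energy + rng.normal(0, energy_noise_sd, T)

    ens = ConformationalEnsemble(
        coords=coords,
        atom_meta=_default_meta(n_atoms),
        superposed=False,
    )
    truth = SyntheticTruth(
        seed=seed,
        mixing_true=np.hstack([dirs, h_dirs]),
        source_labels=which,
        energy_true=energy,
        extras={"well_energies": [w.energy for w in wells]},
    )
    return ens, truth


# ---------------------------------------------------------------------------
# canonical planted-study datasets
# ---------------------------------------------------------------------------

def _two_directions(n_coords: int, cosine: float, rng: np.random.Generator):
    u1 = rng.standard_normal(n_coords)
    u1 /= np.linalg.norm(u1)
    v = rng.standard_normal(n_coords)
    v -= (v @ u1) * u1
    v /= np.linalg.norm(v)
    u2 = cosine * u1 + np.sqrt(1 - cosine**2) * v
    return u1, u2


def nested_substates(n_atoms: int = 40, T: int = 4000, seed: int = 0):
    """Two-level planted mixture: well A (sub-wells A1/A2) plus well B.

    The A|B split dominates the level-1 landscape; the A1|A2 split has a
    smaller amplitude than the two planted Gaussian collective modes, so
    it only surfaces when the A branch is re-decomposed -- a minimal
    emulation of the multi-level sub-state hierarchy seen in proteins.
    Returns (ensemble, truth) with truth.source_labels in {0: A1, 1: A2,
    2: B}.
    """
    rng = np.random.default_rng((seed, 101))  # distinct stream from the frame sampler
    u1, u2 = _two_directions(3 * n_atoms, 0.4, rng)
    c_ab, c_sub = 3.0, 1.2
    centers = [c_ab * u1 + c_sub * u2, c_ab * u1 - c_sub * u2, -c_ab * u1]
    energies = [-1.0, 0.0, 1.0]
    wells = [
        Well(direction=c, magnitude=np.linalg.norm(c), energy=e, weight=w)
        for c, e, w in zip(centers, energies, [0.35, 0.35, 0.30])
    ]
    return make_toy_ensemble(
        n_atoms,
        wells,
        noise_sd=0.15,
        T=T,
        seed=seed,
        jitter_sd=0.3,
        harmonic_modes=2,
        harmonic_sd=2.2,
        energy_noise_sd=0.25,
    )


def anharmonic_energy_wells(n_atoms: int = 40, T: int = 4000, seed: int = 0):
    """Three wells along non-orthogonal directions with planted energies.

    Designed so variance ranking misorders the landscape: the
    non-orthogonal well directions push one covariance eigenvalue above
    and one below the planted source variances, and the two Gaussian
    collective modes (sd 2.3 A) sit in between.  A top-3 variance
    (quasi-harmonic) projection therefore drops the minor sub-state
    direction while a top-3 amplitude (anharmonic) projection keeps it,
    which is what makes the planted energy structure separable by the
    anharmonic decomposition only.
    """
    rng = np.random.default_rng((seed, 202))  # distinct stream from the frame sampler
    u1, u2 = _two_directions(3 * n_atoms, 0.4, rng)
    centers = [3.0 * u1 + 2.8 * u2, 3.0 * u1 - 2.8 * u2, -3.0 * u1]
    energies = [-1.0, 0.0, 1.0]
    wells = [
        Well(direction=c, magnitude=np.linalg.norm(c), energy=e, weight=w)
        for c, e, w in zip(centers, energies, [0.35, 0.35, 0.30])
    ]
    return make_toy_ensemble(
        n_atoms,
        wells,
        noise_sd=0.15,
        T=T,
        seed=seed,
        jitter_sd=1.2,
        harmonic_modes=2,
        harmonic_sd=2.3,
        energy_noise_sd=0.25,
    )


# ---------------------------------------------------------------------------
# umbrella-window reaction-pathway emulator
# ---------------------------------------------------------------------------

def _extend_chain(a, b, c, bond, angle_deg, dihedral_deg):
    """Place the next atom at given bond/angle/dihedral (NeRF construction)."""
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    mvec = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            -bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d2[0] * bc + d2[1] * mvec + d2[2] * n


def _build_chain(n_atoms: int, central_dihedral: float, bond: float = 1.5,
                 angle: float = 110.0) -> np.ndarray:
    """Extended bead chain whose central dihedral is set explicitly."""
    pos = np.zeros((n_atoms, 3))
    pos[1] = [bond, 0.0, 0.0]
    ang = np.radians(180.0 - angle)
    pos[2] = pos[1] + bond * np.array([np.cos(ang), np.sin(ang), 0.0])
    central = n_atoms // 2 - 1  # dihedral over atoms central-1 .. central+2
    for idx in range(3, n_atoms):
        dih = central_dihedral if idx == central + 2 else 180.0
        pos[idx] = _extend_chain(pos[idx - 3], pos[idx - 2], pos[idx - 1], bond, angle, dih)
    return pos


def make_reaction_pathway(
    omega_start_deg: float = 180.0,
    omega_end_deg: float = 0.0,
    step_deg: float = 5.0,
    frames_per_window: int = 500,
    chain_length: int = 8,
    jitter_sd_deg: float = 2.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[ConformationalEnsemble, AnnotationTrack, SyntheticTruth]:
    """Umbrella-window emulator for a dihedral reaction coordinate.

    Windows are placed at omega = start, start - step, ..., end
    (inclusive; the step must divide the sweep).  Each window restrains
    the central dihedral of a toy bead chain to the window's omega with
    harmonic (Gaussian) jitter.  Defaults replicate a trans (180 deg) to
    cis (0 deg) isomerization swept in 5-degree decrements with 500
    conformations per window: 37 windows, 18,500 frames in total.
    """
    sweep = omega_start_deg - omega_end_deg
    n_steps = sweep / step_deg
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step_deg must divide the sweep exactly")
    if frames_per_window < 1:
        raise ValueError("frames_per_window must be >= 1")
    omegas = omega_start_deg - step_deg * np.arange(int(round(n_steps)) + 1)

    rng = np.random.default_rng(seed)
    frames = []
    omega_track = []
    window_id = []
    for w, omega in enumerate(omegas):
        jit = rng.normal(0, jitter_sd_deg, frames_per_window)
        for dj in jit:
            chain = _build_chain(chain_length, omega + dj)
            chain = chain + rng.normal(0, noise_sd, chain.shape)
            frames.append(chain)
            omega_track.append(omega + dj)
            window_id.append(w)

    coords = np.stack(frames)
    ens = ConformationalEnsemble(
        coords=coords, atom_meta=_default_meta(chain_length), superposed=False
    )
    track = AnnotationTrack(name="omega", values=np.array(omega_track), units="deg")
    truth = SyntheticTruth(
        seed=seed,
        window_id=np.array(window_id),
        extras={
            "window_omegas": omegas.tolist(),
            "n_windows": len(omegas),
            "central_dihedral_atoms": tuple(
                chain_length // 2 - 2 + i for i in range(4)
            ),
        },
    )
    return ens, track, truth
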