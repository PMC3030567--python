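"""Conformational-ensemble I/O, superposition and deviation matrices.

An ensemble is a stack of conformations (frames x atoms x 3, in angstrom)
of the same atom selection.  All downstream analysis consumes the
mean-removed deviation matrix ``X`` (frames x 3n, x/y/z interleaved per
atom) produced after iterative rigid-body superposition onto the mean
structure, so that positional deviations measure internal motion only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomSelection",
    "ConformationalEnsemble",
    "DeviationMatrix",
    "read_ensemble",
    "superpose_ensemble",
    "compute_deviations",
    "write_ensemble_pdb",
    "write_mode_animation",
    "write_deviations",
    "read_deviations",
]


@dataclass(frozen=True)
class AtomSelection:
    """A resolved atom selection: expression plus 0-based atom indices."""

    expression: str
    resolved_indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.resolved_indices, dtype=int)
        if idx.size == 0:
            raise ValueError(f"selection {self.expression!r} matches no atoms")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("selection indices must be strictly increasing")
        object.__setattr__(self, "resolved_indices", idx)

    def __len__(self) -> int:
        return int(self.resolved_indices.size)


@dataclass
class ConformationalEnsemble:
    """Frames x atoms x 3 coordinates (angstrom) with per-atom metadata.

    ``atom_meta`` is a DataFrame with columns name, resname, resid, chain.
    ``superposed`` records whether frames have been rigid-body superposed
    onto the iteratively refined mean structure.
    """

    coords: np.ndarray
    atom_meta: pd.DataFrame
    frame_spacing: float | None = None
    selection: AtomSelection | None = None
    superposed: bool = False
    superposition_rmsd: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("ensemble needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.atom_meta) != self.coords.shape[1]:
            raise ValueError("atom_meta length must equal atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def mean_structure(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class DeviationMatrix:
    """Mean-removed positional deviations X (frames x 3n, angstrom)."""

    X: np.ndarray
    mean_structure: np.ndarray
    selection: AtomSelection | None = None
    superposition_rmsd: np.ndarray | None = None
    atom_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        col_means = self.X.mean(axis=0)
        if np.abs(col_means).max() > 1e-8:
            raise ValueError("deviation columns must have zero mean (<= 1e-8 A)")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_coords(self) -> int:
        return self.X.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.X.shape[1] // 3

    def atom_deviations(self, atom: int) -> np.ndarray:
        """Per-frame 3-vector deviations of one atom (frames x 3)."""
        if not 0 <= atom < self.n_atoms:
            raise IndexError(f"atom {atom} out of range (n={self.n_atoms})")
        return self.X[:, 3 * atom: 3 * atom + 3]

    @classmethod
    def from_matrix(cls, X: np.ndarray) -> "DeviationMatrix":
        """Wrap a plain observation matrix, centering its columns."""
        X = np.asarray(X, dtype=float)
        Xc = X - X.mean(axis=0)
        n = X.shape[1] // 3 if X.shape[1] % 3 == 0 else X.shape[1]
        mean = np.zeros((n, 3)) if X.shape[1] % 3 == 0 else np.zeros((X.shape[1], 3))
        return cls(X=Xc, mean_structure=mean)

    def subset(self, frames: np.ndarray) -> "DeviationMatrix":
        """Restrict to a frame subset, re-centering columns."""
        Xs = self.X[np.asarray(frames, dtype=int)]
        sub_mean = Xs.mean(axis=0)
        out = DeviationMatrix.__new__(DeviationMatrix)
        out.X = Xs - sub_mean
        if self.X.shape[1] % 3 == 0:
            out.mean_structure = self.mean_structure + sub_mean.reshape(-1, 3)
        else:
            out.mean_structure = self.mean_structure
        out.selection = self.selection
        out.superposition_rmsd = None
        out.atom_meta = self.atom_meta
        return out


def _universe_meta(ag) -> pd.DataFrame:
    def _get(attr, default):
        try:
            return list(getattr(ag, attr))
        except Exception:
            return [default] * len(ag)

    return pd.DataFrame(
        {
            "name": _get("names", "X"),
            "resname": _get("resnames", "UNK"),
            "resid": _get("resids", 1),
            "chain": [str(s) for s in _get("segids", "A")],
        }
    )


def read_ensemble(
    paths: str | Path | Sequence[str | Path],
    topology: str | Path | None = None,
    selection: str = "all",
) -> ConformationalEnsemble:
    """Read a multi-model PDB (or DCD/XTC + PDB topology) into an ensemble.

    Multiple input files are concatenated in argument order.  The returned
    ensemble is restricted to ``selection`` (MDAnalysis grammar, e.g.
    ``"name CA and resid 2:70"``); frames keep file order.
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    for p in list(paths) + ([Path(topology)] if topology else []):
        if not p.exists():
            raise FileNotFoundError(p)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if topology is not None:
            universes = [mda.Universe(str(topology), [str(p) for p in paths])]
        else:
            universes = [mda.Universe(str(p)) for p in paths]

        frames: list[np.ndarray] = []
        meta = None
        dt = None
        n_sel = None
        for u in universes:
            ag = u.select_atoms(selection)
            if len(ag) == 0:
                raise ValueError(f"selection {selection!r} matches no atoms")
            if n_sel is None:
                n_sel = len(ag)
                meta = _universe_meta(ag)
                indices = np.asarray(ag.indices, dtype=int)
                try:
                    dt = float(u.trajectory.dt)
                except Exception:
                    dt = None
            elif len(ag) != n_sel:
                raise ValueError(
                    f"atom-count mismatch across inputs: {len(ag)} vs {n_sel}"
                )
            for _ in u.trajectory:
                frames.append(ag.positions.astype(float).copy())

    if not frames:
        raise ValueError("zero frames read")
    sel = AtomSelection(expression=selection, resolved_indices=indices)
    return ConformationalEnsemble(
        coords=np.stack(frames),
        atom_meta=meta,
        frame_spacing=dt,
        selection=sel,
    )


def _kabsch(ref: np.ndarray, mobile: np.ndarray) -> np.ndarray:
    """Proper rotation (det = +1) aligning centered ``mobile`` onto ``ref``."""
    rot, _ = Rotation.align_vectors(ref, mobile)
    return rot.as_matrix()


def superpose_ensemble(
    ens: ConformationalEnsemble,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> ConformationalEnsemble:
    """Rigid-body superpose every frame onto the iteratively refined mean.

    Each frame is translated to its centroid and rotated (Kabsch, proper
    rotation only -- no reflection) onto the running mean structure; the
    mean is recomputed until it moves less than ``tol`` RMSD or
    ``max_iter`` iterations.  Mirror-image frames therefore retain a
    nonzero residual RMSD.
    """
    coords = ens.coords - ens.coords.mean(axis=1, keepdims=True)
    n = ens.n_atoms
    for t in range(ens.n_frames):
        s = np.linalg.svd(coords[t], compute_uv=False)
        if s[1] < 1e-10:
            raise ValueError(f"degenerate frame {t}: atoms collinear or coincident")

    # start from the raw mean so an already-superposed ensemble is an
    # exact fixed point; fall back to frame 0 when rotational smearing
    # degenerates the raw mean (e.g. randomly oriented frames)
    ref = coords.mean(axis=0)
    if np.linalg.svd(ref, compute_uv=False)[1] < 1e-6:
        ref = coords[0]
    aligned = coords.copy()
    for _ in range(max_iter):
        for t in range(len(coords)):
            aligned[t] = coords[t] @ _kabsch(ref, coords[t]).T
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        shift = np.sqrt(((new_mean - ref) ** 2).sum() / n)
        ref = new_mean
        if shift < tol:
            break

    for t in range(len(coords)):
        aligned[t] = coords[t] @ _kabsch(ref, coords[t]).T
    rmsd = np.sqrt(((aligned - ref) ** 2).sum(axis=(1, 2)) / n)
    return ConformationalEnsemble(
        coords=aligned,
        atom_meta=ens.atom_meta,
        frame_spacing=ens.frame_spacing,
        selection=ens.selection,
        superposed=True,
        superposition_rmsd=rmsd,
    )


def compute_deviations(ens: ConformationalEnsemble) -> DeviationMatrix:
    """Flatten superposed frames into the mean-removed deviation matrix."""
    if not ens.superposed:
        raise ValueError(
            "ensemble must be superposed first (call superpose_ensemble)"
        )
    mean = ens.mean_structure()
    X = (ens.coords - mean).reshape(ens.n_frames, 3 * ens.n_atoms)
    X = X - X.mean(axis=0)  # exact centering against float round-off
    return DeviationMatrix(
        X=X,
        mean_structure=mean,
        selection=ens.selection,
        superposition_rmsd=ens.superposition_rmsd,
        atom_meta=ens.atom_meta,
    )


def _default_meta(n_atoms: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": ["CA"] * n_atoms,
            "resname": ["GLY"] * n_atoms,
            "resid": np.arange(1, n_atoms + 1),
            "chain": ["A"] * n_atoms,
        }
    )


def write_ensemble_pdb(
    coords: np.ndarray,
    path: str | Path,
    atom_meta: pd.DataFrame | None = None,
) -> None:
    """Write a (frames x atoms x 3) stack as a multi-model PDB."""
    import MDAnalysis as mda

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    meta = atom_meta if atom_meta is not None else _default_meta(n_atoms)

    resid_chain = list(zip(meta["resid"], meta["chain"]))
    residues = list(dict.fromkeys(resid_chain))
    res_index = {rc: i for i, rc in enumerate(residues)}
    atom_resindex = np.array([res_index[rc] for rc in resid_chain])
    res_meta = meta.drop_duplicates(subset=["resid", "chain"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms,
            n_residues=len(residues),
            atom_resindex=atom_resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", list(meta["name"]))
        u.add_TopologyAttr("resnames", list(res_meta["resname"]))
        u.add_TopologyAttr("resids", list(res_meta["resid"]))
        u.add_TopologyAttr("chainIDs", [str(c)[:1] for c in meta["chain"]])
        with mda.Writer(str(path), n_atoms, multiframe=True) as w:
            for frame in coords:
                u.atoms.positions = frame
                w.write(u.atoms)


def write_mode_animation(
    mean_structure: np.ndarray,
    mode_vector: np.ndarray,
    amplitude: float,
    n_frames: int,
    out: str | Path,
    atom_meta: pd.DataFrame | None = None,
) -> None:
    """Sweep ``mean + a * unit(mode)`` for a in [-amplitude, +amplitude].

    Writes a multi-model PDB with ``n_frames`` (odd, >= 3) linearly spaced
    models; the middle model is the mean structure itself, giving the
    movie-like back-and-forth rendering of one mode of motion.
    """
    mode = np.asarray(mode_vector, dtype=float).ravel()
    norm = np.linalg.norm(mode)
    if norm == 0:
        raise ValueError("mode_vector must be nonzero")
    if n_frames < 3 or n_frames % 2 == 0:
        raise ValueError("n_frames must be odd and >= 3")
    mean = np.asarray(mean_structure, dtype=float)
    unit = (mode / norm).reshape(mean.shape)
    amps = np.linspace(-amplitude, amplitude, n_frames)
    frames = mean[None] + amps[:, None, None] * unit[None]
    write_ensemble_pdb(frames, out, atom_meta=atom_meta)


def write_deviations(dev: DeviationMatrix, path: str | Path) -> None:
    """Export X as whitespace-delimited text with a one-line header."""
    with open(path, "w") as fh:
        fh.write(f"# frames {dev.n_frames} coords {dev.n_coords}\n")
        np.savetxt(fh, dev.X, fmt="%.8g")


def read_deviations(path: str | Path) -> DeviationMatrix:
    X = np.loadtxt(path, comments="#")
    return DeviationMatrix.from_matrix(X)
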