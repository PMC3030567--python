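"""Per-frame annotation tracks used to paint sub-state landscapes.

Tracks are scalar observables per frame: externally computed internal
energies, C-alpha distance order parameters (e.g. a binding-cleft
opening distance), or a dihedral reaction coordinate (e.g. the amide
omega angle of a cis/trans isomerization, trans = 180 deg, cis = 0).
Energies are consumed, never computed here.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ensembles import ConformationalEnsemble

__all__ = [
    "AnnotationTrack",
    "scale_annotation",
    "ca_distance_track",
    "dihedral_track",
    "read_annotation",
]


@dataclass
class AnnotationTrack:
    name: str
    values: np.ndarray
    units: str = ""
    scaled: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.scaled:
            ok = np.isfinite(self.values)
            if abs(self.values[ok].mean()) > 1e-8 or abs(self.values[ok].std() - 1) > 1e-8:
                raise ValueError("scaled track must be zero-mean, unit-variance")

    def __len__(self) -> int:
        return self.values.size


def scale_annotation(track: AnnotationTrack) -> AnnotationTrack:
    """Z-score a track (population sigma) for painting landscapes."""
    v = track.values
    sigma = v.std()
    if sigma <= 0:
        raise ValueError(f"constant track {track.name!r} cannot be scaled")
    return AnnotationTrack(
        name=track.name, values=(v - v.mean()) / sigma, units="sigma", scaled=True
    )


def _ca_index(ens: ConformationalEnsemble, resid: int) -> int:
    meta = ens.atom_meta
    hits = np.where((meta["name"] == "CA") & (meta["resid"] == resid))[0]
    if hits.size == 0:
        raise ValueError(f"residue {resid} has no CA atom in the selection")
    return int(hits[0])


def ca_distance_track(
    ens: ConformationalEnsemble, residue_i: int, residue_j: int
) -> AnnotationTrack:
    """Per-frame C-alpha--C-alpha distance between two residues (A)."""
    ai = _ca_index(ens, residue_i)
    aj = _ca_index(ens, residue_j)
    d = np.linalg.norm(ens.coords[:, ai] - ens.coords[:, aj], axis=1)
    return AnnotationTrack(name=f"d_CA_{residue_i}_{residue_j}", values=d, units="A")


def dihedral_track(ens: ConformationalEnsemble, atoms: tuple[int, int, int, int]) -> AnnotationTrack:
    """Signed dihedral over the four given atom indices, degrees (-180, 180].

    Standard atan2 construction; collinear triples yield NaN for that
    frame.  Mirror-imaging a frame flips the sign (chirality).
    """
    i, j, k, l = atoms
    if len({i, j, k, l}) != 4:
        raise ValueError("four distinct atoms required")
    p0, p1, p2, p3 = (ens.coords[:, a] for a in (i, j, k, l))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1n = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
        x = np.einsum("ti,ti->t", n1, n2)
        y = np.einsum("ti,ti->t", np.cross(n1, b1n), n2)
        ang = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=1) < 1e-10) | (np.linalg.norm(n2, axis=1) < 1e-10)
    ang[bad] = np.nan
    # fold -180 onto +180 so the range is (-180, 180]
    ang[ang <= -180.0 + 1e-12] = 180.0
    return AnnotationTrack(name="dihedral", values=ang, units="deg")


def read_annotation(
    path: str | Path, n_frames: int | None = None, name: str | None = None
) -> AnnotationTrack:
    """Read a per-frame scalar track from delimited text.

    Accepts one value per line or (frame, value) pairs; a single
    non-numeric header line is skipped.  If ``n_frames`` is given the
    track length must match it exactly.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if lines and not lines[0].lstrip("-+")[:1].isdigit() and not lines[0].startswith("."):
        lines = lines[1:]
    rows = []
    for ln in lines:
        parts = ln.replace(",", " ").split()
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"non-numeric value in {path}: {ln!r}") from exc
    if not rows:
        raise ValueError(f"no data in {path}")
    arr = np.array(rows)
    if arr.shape[1] == 1:
        values = arr[:, 0]
    else:
        order = np.argsort(arr[:, 0])
        values = arr[order, 1]
    if n_frames is not None and values.size != n_frames:
        raise ValueError(
            f"annotation length {values.size} does not match frame count {n_frames}"
        )
    return AnnotationTrack(name=name or path.stem, values=values)
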