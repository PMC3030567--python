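"""Conformational sub-state identification and hierarchical recursion.

Sub-states (valleys of the conformational landscape) are identified by
mixture-of-Gaussians clustering in the top anharmonic-mode projection.
The landscape hierarchy is built by recursing into the most populous
sub-state: its frames are re-decomposed (quasi-harmonic reduction, then
the anharmonic rotation) and re-clustered, so each level resolves
progressively more local, energetically homogeneous structure.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ensembles import ConformationalEnsemble, DeviationMatrix
from .jade import AnharmonicBasis, project_anharmonic, qaa_decompose

__all__ = [
    "ClusterModel",
    "Ellipsoid",
    "SubstateNode",
    "SubstateTree",
    "HierarchyParams",
    "fit_mog",
    "assign_substates",
    "place_external_ensemble",
    "recurse_hierarchy",
    "homogeneity_comparison",
]


@dataclass
class ClusterModel:
    """Fitted mixture-of-Gaussians over a low-dimensional projection."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    bic: float
    seed: int
    _gm: object = field(repr=False, default=None)


@dataclass
class Ellipsoid:
    """A cluster boundary: Mahalanobis distance <= radius under one component."""

    mean: np.ndarray
    covariance: np.ndarray
    radius: float = 3.0


def fit_mog(
    points: np.ndarray,
    k: int | str = "auto",
    seed: int = 0,
    n_init: int = 20,
    k_max: int = 8,
    tol: float = 1e-7,
    reg_scale: float = 1e-6,
) -> ClusterModel:
    """EM fit of a full-covariance Gaussian mixture.

    k-means++ initialization with ``n_init`` restarts, best likelihood
    kept; ``k="auto"`` selects the component count in 1..k_max by
    minimum BIC.  Covariances are regularized by reg_scale * trace / d
    on the diagonal.
    """
    from sklearn.mixture import GaussianMixture

    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    T, d = pts.shape
    reg = reg_scale * float(np.trace(np.cov(pts.T).reshape(d, d))) / d
    reg = max(reg, 1e-12)

    def _fit(kk: int) -> GaussianMixture:
        if T <= 10 * kk:
            raise ValueError(f"too few points ({T}) for k={kk} (need > 10k)")
        gm = GaussianMixture(
            n_components=kk,
            covariance_type="full",
            n_init=n_init,
            init_params="k-means++",
            tol=tol,
            reg_covar=reg,
            max_iter=500,
            random_state=seed,
        )
        gm.fit(pts)
        return gm

    if k == "auto":
        best, best_bic = None, np.inf
        for kk in range(1, k_max + 1):
            if T <= 10 * kk:
                break
            gm = _fit(kk)
            bic = gm.bic(pts)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
        gm = best
    else:
        gm = _fit(int(k))

    return ClusterModel(
        k=gm.n_components,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        log_likelihood=float(gm.score(pts) * T),
        bic=float(gm.bic(pts)),
        seed=seed,
        _gm=gm,
    )


def _mahalanobis(points: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Mahalanobis distance of each point to each component (T x k)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty((pts.shape[0], model.k))
    for c in range(model.k):
        diff = pts - model.means[c]
        inv = np.linalg.inv(model.covariances[c])
        out[:, c] = np.sqrt(np.einsum("ti,ij,tj->t", diff, inv, diff))
    return out


def assign_substates(
    points: np.ndarray, model: ClusterModel
) -> tuple[np.ndarray, list[Ellipsoid]]:
    """Hard labels by maximum posterior plus per-cluster 3-sigma ellipsoids."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[1] != model.means.shape[1]:
        raise ValueError("dimension mismatch between points and model")
    labels = model._gm.predict(pts)
    ellipsoids = [
        Ellipsoid(mean=model.means[c], covariance=model.covariances[c], radius=3.0)
        for c in range(model.k)
    ]
    return labels, ellipsoids


def place_external_ensemble(
    ext: ConformationalEnsemble,
    basis: AnharmonicBasis,
    model: ClusterModel,
    mean_structure: np.ndarray,
    k_sigma: float = 2.0,
):
    """Project external structures into a level's sub-state space.

    The external ensemble must already be superposed onto the reference
    (MD) mean structure and restricted to the same atom selection.  Each
    structure is projected through the level's demixing map (top-d
    modes, d from the fitted model) and scored by Mahalanobis distance
    against every mixture component; ``cluster`` is the closest one.
    """
    import pandas as pd

    if ext.coords.shape[1] * 3 != basis.demixing.shape[1]:
        raise ValueError("external ensemble atom count does not match basis")
    d = model.means.shape[1]
    Xe = (ext.coords - np.asarray(mean_structure)).reshape(ext.n_frames, -1)
    proj = Xe @ basis.demixing[:d].T
    maha = _mahalanobis(proj, model)
    cluster = maha.argmin(axis=1)
    best = maha[np.arange(len(proj)), cluster]
    return pd.DataFrame(
        {
            "structure": np.arange(ext.n_frames),
            "cluster": cluster,
            "mahalanobis": best,
            "within_k_sigma": best <= k_sigma,
        }
    )


@dataclass
class HierarchyParams:
    """Knobs of the hierarchical decomposition.

    d modes per level (projection dimensionality for clustering),
    variance target + cap for the quasi-harmonic pre-projection, the
    mixture size k ("auto" = BIC), and the recursion policy (most
    populous sub-state by default; "annotation_variance" follows the
    sub-state with the most heterogeneous annotation instead).
    """

    max_depth: int = 4
    n_modes: int = 3
    variance_target: float = 0.9
    max_qha_modes: int | None = 30
    k: int | str | Sequence[int | str] = "auto"
    min_size: int = 100
    seed: int = 0
    recurse_on: str = "population"
    recurse_annotation: str | None = None

    def k_at(self, level: int) -> int | str:
        if isinstance(self.k, (int, str)):
            return self.k
        ks = list(self.k)
        return ks[min(level - 1, len(ks) - 1)]


@dataclass
class SubstateNode:
    """One sub-state: a cluster of frames at one hierarchy level."""

    level: int
    cluster_id: int
    member_frames: np.ndarray
    population: int
    annotation_stats: dict = field(default_factory=dict)
    ellipsoid: Ellipsoid | None = None
    basis: AnharmonicBasis | None = None      # decomposition *of* this node
    model: ClusterModel | None = None
    projection: np.ndarray | None = None
    labels: np.ndarray | None = None
    children: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "level": self.level,
            "cluster_id": int(self.cluster_id),
            "population": int(self.population),
            "annotation_stats": {
                k: {"mean": float(v[0]), "std": float(v[1])}
                for k, v in self.annotation_stats.items()
            },
            "children": [c.to_dict() for c in self.children],
        }
        if self.ellipsoid is not None:
            d["ellipsoid"] = {
                "mean": self.ellipsoid.mean.tolist(),
                "covariance": self.ellipsoid.covariance.tolist(),
                "radius": self.ellipsoid.radius,
            }
        return d


@dataclass
class SubstateTree:
    root: SubstateNode
    params: HierarchyParams

    def to_json(self, path=None, **kwargs) -> str:
        s = json.dumps(self.root.to_dict(), **({"indent": 2} | kwargs))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def levels(self) -> list[list[SubstateNode]]:
        """Nodes grouped by level (root excluded)."""
        out: dict[int, list[SubstateNode]] = {}
        stack = [self.root]
        while stack:
            n = stack.pop()
            for c in n.children:
                out.setdefault(c.level, []).append(c)
                stack.append(c)
        return [sorted(out[l], key=lambda n: n.cluster_id) for l in sorted(out)]

    def leaf_assignment(self) -> tuple[np.ndarray, list]:
        """Per-frame index into the tree's leaves (finest partition).

        Every frame belongs to exactly one leaf; leaves are the
        non-decomposed sub-states across all levels.
        """
        leaves: list[SubstateNode] = []

        def walk(n: SubstateNode) -> None:
            if n.children:
                for c in n.children:
                    walk(c)
            else:
                leaves.append(n)

        walk(self.root)
        out = np.full(self.root.population, -1, dtype=int)
        for i, leaf in enumerate(leaves):
            out[leaf.member_frames] = i
        return out, leaves

    def assignments(self) -> "np.ndarray":
        """(frame, level, cluster) rows for every decomposed level."""
        rows = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            for c in n.children:
                for f in c.member_frames:
                    rows.append((int(f), c.level, int(c.cluster_id)))
                stack.append(c)
        return np.array(sorted(rows), dtype=int)


def _annotation_stats(
    annotations: Mapping[str, np.ndarray] | None, frames: np.ndarray
) -> dict:
    if not annotations:
        return {}
    return {
        name: (float(np.mean(vals[frames])), float(np.std(vals[frames])))
        for name, vals in annotations.items()
    }


def _decompose_node(
    dev: DeviationMatrix,
    node: SubstateNode,
    params: HierarchyParams,
    annotations: Mapping[str, np.ndarray] | None,
) -> None:
    sub = dev.subset(node.member_frames)
    ab = qaa_decompose(
        sub,
        variance_target=params.variance_target,
        max_modes=params.max_qha_modes,
    )
    d = min(params.n_modes, ab.m)
    proj = project_anharmonic(sub, ab, d)
    model = fit_mog(proj, k=params.k_at(node.level + 1), seed=params.seed)
    labels, ellipsoids = assign_substates(proj, model)
    node.basis = ab
    node.model = model
    node.projection = proj
    node.labels = labels
    for c in range(model.k):
        frames_c = node.member_frames[labels == c]
        node.children.append(
            SubstateNode(
                level=node.level + 1,
                cluster_id=c,
                member_frames=frames_c,
                population=len(frames_c),
                annotation_stats=_annotation_stats(annotations, frames_c),
                ellipsoid=ellipsoids[c],
            )
        )


def _recursion_target(
    node: SubstateNode,
    params: HierarchyParams,
    annotations: Mapping[str, np.ndarray] | None,
) -> SubstateNode:
    if params.recurse_on == "annotation_variance":
        name = params.recurse_annotation
        if name is None or not annotations or name not in annotations:
            raise ValueError("recurse_on='annotation_variance' needs a named track")
        return max(node.children, key=lambda c: c.annotation_stats[name][1])
    return max(node.children, key=lambda c: c.population)


def recurse_hierarchy(
    dev: DeviationMatrix,
    params: HierarchyParams | None = None,
    annotations: Mapping[str, np.ndarray] | None = None,
) -> SubstateTree:
    """Build the multi-level sub-state hierarchy.

    At each level the chosen node's frames are re-centered and fully
    re-decomposed (quasi-harmonic reduction, anharmonic rotation,
    mixture clustering in the top-d source projection); recursion
    descends into the most populous sub-state and stops at ``max_depth``
    levels, when the target is smaller than ``min_size``, or when a
    single component is selected.
    """
    params = params or HierarchyParams()
    if annotations:
        for name, vals in annotations.items():
            if len(vals) != dev.n_frames:
                raise ValueError(f"annotation {name!r} length mismatch")
    all_frames = np.arange(dev.n_frames)
    root = SubstateNode(
        level=0,
        cluster_id=-1,
        member_frames=all_frames,
        population=dev.n_frames,
        annotation_stats=_annotation_stats(annotations, all_frames),
    )
    node = root
    for _ in range(params.max_depth):
        _decompose_node(dev, node, params, annotations)
        target = _recursion_target(node, params, annotations)
        if target.population < params.min_size or node.model.k == 1:
            break
        if target.population <= 10 * 2:  # cannot fit even k=2 below this
            break
        node = target
    return SubstateTree(root=root, params=params)


def homogeneity_comparison(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    annotation: np.ndarray,
) -> dict:
    """Compare two labelings of the same frames on one annotation track.

    Reports per-cluster annotation mean/std for both labelings and the
    population-weighted within-cluster variance; a lower value means the
    clustering carved out more homogeneous sub-states.
    """
    la, lb = np.asarray(labels_a), np.asarray(labels_b)
    ann = np.asarray(annotation, dtype=float)
    if not (len(la) == len(lb) == len(ann)):
        raise ValueError("labelings and annotation must have equal length")

    def _side(labels):
        clusters = []
        wvar = 0.0
        for c in np.unique(labels):
            vals = ann[labels == c]
            clusters.append(
                {
                    "cluster": int(c),
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "std": float(vals.std()),
                }
            )
            wvar += vals.size / ann.size * float(vals.var())
        return clusters, wvar

    ca, wa = _side(la)
    cb, wb = _side(lb)
    return {
        "a": {"clusters": ca, "within_cluster_variance": wa},
        "b": {"clusters": cb, "within_cluster_variance": wb},
    }
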