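# qaa — quasi-anharmonic analysis of conformational ensembles

Proteins explore their conformational landscape through internal
motions that are not harmonic: atoms hop between wells, sample flat or
double-well potentials, and couple along directions that need not be
orthogonal.  Standard quasi-harmonic analysis (QHA — PCA of the
positional-deviation covariance) removes only second-order
correlations, so it cannot separate the landscape into the
energetically coherent sub-states that matter for binding and
catalysis.

`qaa` implements **quasi-anharmonic analysis**: after whitening the
positional fluctuations, an extra orthogonal rotation V is chosen to
jointly diagonalize the fourth-order cumulant matrices of the whitened
projections (Jacobi/Givens sweeps — the JADE strategy from independent
component analysis).  This yields:

- anharmonic modes of motion **a_i** (columns of the mixing matrix
  A = E Λ<sup>1/2</sup> V, in Å), generally **non-orthogonal**, sorted by
  amplitude ‖a_i‖;
- unit-variance anharmonic sources s = Γx with Γ = V<sup>T</sup> Λ<sup>-1/2</sup> E<sup>T</sup>,
  decorrelated to both second and (approximately) fourth order;
- a hierarchy of conformational **sub-states**: mixture-of-Gaussians
  clustering in the top-3 source projection, recursing into the most
  populous cluster with a fresh decomposition per level;
- anharmonicity diagnostics per atom: raw kurtosis
  γ = E[(x−μ)⁴]/σ⁴ (Gaussian 3, sub-Gaussian < 3, super-Gaussian > 3),
  3σ tail occupancy, and local principal-frame classification;
- annotation "painting": per-frame internal energies, Cα–Cα order
  parameters and dihedral reaction coordinates attached to sub-states.

The package is aimed at people analysing MD ensembles (multi-model
PDB, or DCD/XTC with a PDB topology) who want sub-state structure
beyond what PCA/essential dynamics offers, and it ships synthetic
generators with planted ground truth so every stage is testable
without trajectories.

## Worked example

Generate a toy polymer ensemble with a planted two-level well
structure (a major well containing two sub-wells, plus a separate
minor well, on top of two Gaussian collective modes), decompose it and
build the sub-state hierarchy painted by the planted per-frame energy:

```python
import numpy as np
from qaa import (nested_substates, superpose_ensemble, compute_deviations,
                 qaa_decompose, coupling_matrix, recurse_hierarchy,
                 HierarchyParams)

ens, truth = nested_substates(seed=0)          # 4000 frames, 40 beads
dev = compute_deviations(superpose_ensemble(ens))
ab = qaa_decompose(dev, variance_target=0.9, max_modes=30)
print("whitened dimensions retained:", ab.m)
print("top-5 anharmonic-mode amplitudes (A):", np.round(ab.amplitudes[:5], 2))
print("mode 1-2 coupling:", round(coupling_matrix(ab).c[0, 1], 3))

tree = recurse_hierarchy(dev, HierarchyParams(max_depth=2, k=(2, 2), seed=0),
                         annotations={"energy": truth.energy_true})
for lvl, nodes in enumerate(tree.levels(), start=1):
    for n in nodes:
        mu, sd = n.annotation_stats["energy"]
        print(f"level {lvl} cluster {n.cluster_id}: {n.population} frames, "
              f"energy {mu:+.2f} +- {sd:.2f}")
```

Output:

```
whitened dimensions retained: 19
top-5 anharmonic-mode amplitudes (A): [2.3  1.83 1.62 1.24 1.14]
mode 1-2 coupling: 0.793
level 1 cluster 0: 2820 frames, energy -0.49 +- 0.57
level 1 cluster 1: 1180 frames, energy +1.00 +- 0.25
level 2 cluster 0: 1409 frames, energy +0.02 +- 0.25
level 2 cluster 1: 1411 frames, energy -1.01 +- 0.25
```

Level 1 separates the minor well (1180 frames, energy +1.00, already
homogeneous at the planted energy-noise level ±0.25) from the
heterogeneous major well (energy spread ±0.57).  Re-decomposing the
major well at level 2 splits it into its two planted sub-wells
(energies 0 and −1), each now homogeneous — the successive energetic
homogenization that motivates the method.  The 0.79 coupling between
the top two modes reflects the planted non-orthogonality of the well
directions.

The same pipeline runs from the shell on trajectory files:

```bash
qaa synth --kind nested --out run/data --seed 0
qaa stats     --input run/data/ensemble.pdb --out run/stats
qaa decompose --input run/data/ensemble.pdb --out run/modes
qaa hierarchy --input run/data/ensemble.pdb --annotation run/data/energy.tsv \
              --k 2 --max-depth 2 --out run/tree
```

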