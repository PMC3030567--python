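# Methods

## Model

Positional deviations x (frames × 3n, Å, mean-removed after iterative
rigid-body superposition) are modelled as a linear combination of
anharmonic sources, x = A s, with A an unknown — generally
non-orthogonal — coupling matrix whose columns are the anharmonic
modes of motion, and s unit-variance sources.  The estimate proceeds
in two stages:

1. **Quasi-harmonic whitening.**  The covariance C = XᵀX/T
   (population normalization, mass-unweighted Cartesian deviations) is
   eigen-decomposed, C = E Λ Eᵀ; the whitening map B = Λ^(−1/2) Eᵀ
   gives projections H = X Bᵀ with identity covariance, removing all
   second-order correlations.  Eigenvalues below 1e-10 of the largest
   are dropped before the inverse square root.  In protein use the
   space is first reduced to a few tens of quasi-harmonic dimensions
   (a variance target, optionally capped at 30 modes by default) both
   to suppress fast local fluctuations and to keep the fourth-order
   statistics estimable.

2. **Joint diagonalization of fourth-order cumulants.**  Whitening
   leaves an orthogonal rotation undetermined (any rotation of white
   data is white).  The rotation V is chosen to approximately
   diagonalize the set of cumulant matrices
   [Q(i,j)]_{k,l} = cum(z_i, z_j, z_k, z_l)
   = E[z_i z_j z_k z_l] − E[z_i z_j]E[z_k z_l]
   − E[z_i z_k]E[z_j z_l] − E[z_i z_l]E[z_j z_k],
   computed with sample moments on the whitened projections.  Jacobi
   sweeps over index pairs apply the closed-form optimal Givens angle
   for the weighted sum of squared off-diagonals (cross-pair matrices
   carry tensor multiplicity 2).  Gaussian data has vanishing fourth
   cumulants, so JADE isolates exactly the non-Gaussian (anharmonic)
   directions; an all-Gaussian input triggers an "unidentifiable
   rotation" warning.

The mixing matrix is A = E Λ^(1/2) V and the demixing map Γ = Vᵀ B,
so Γ A = I and the sources S = X Γᵀ have identity covariance by
construction.  Modes are sorted by decreasing amplitude ‖a_i‖ (the
spatial extent of one unit of source excitation; ties broken by
original index) and sign-fixed so each mode's largest-magnitude entry
is positive.

## Sub-state hierarchy

Sub-states are identified by a full-covariance Gaussian-mixture fit
(EM, k-means++ initialization, 20 restarts, best likelihood kept;
k chosen by minimum BIC over 1..8 unless fixed) in the top-d source
projection, d = 3 by default, matching the visualizable landscape.
Cluster boundaries are reported as 3σ Mahalanobis ellipsoids.  The
hierarchy recurses into the most populous sub-state (optionally the
sub-state with the largest annotation variance): its frames are
re-centered and the *entire* decomposition — quasi-harmonic reduction,
cumulant rotation, mixture fit — is re-run on the subset.  Re-running
per level (rather than reusing level-1 bases) is a deliberate choice:
within a well, the dominant residual motions differ from the global
ones, and the re-decomposition is what exposes sub-structure that is
below the top-d amplitude cut at the parent level.  Recursion stops at
max_depth (default 4), when the target falls below min_size (default
100 frames), or when a single component is selected.

External (e.g. crystallographic or NMR) ensembles are placed into a
level's landscape by superposing them onto the reference mean
structure, projecting through the level's Γ (top-d rows), and scoring
Mahalanobis distances against each mixture component.  Whether such
ensembles should be superposed to the analysis mean is not uniquely
defined; we superpose to the mean structure and note this as a
convention.

## Anharmonicity diagnostics

Raw kurtosis γ = E[(x−μ)⁴]/σ⁴ with population moments (Gaussian
baseline 3; algebraic minimum 1, attained by symmetric two-point
data).  Per-atom classification projects the atom's deviations onto
its own 3×3 covariance eigenframe and labels each local principal
component super-Gaussian (γ > 3 + δ), sub-Gaussian (γ < 3 − δ) or
Gaussian, with δ = 0.3 and an additional significance guard
|γ − 3| > 2·√(24/T) (twice the asymptotic standard error of the
Gaussian kurtosis estimate) so that sampling noise is never labelled
anharmonic.  Local components with eigenvalue below 1e-12 are flagged
undefined.  Tail occupancy fits a Gaussian by the sample mean and σ of
the full series and reports the two-sided mass beyond 3σ (0.0027 for
Gaussian data); the per-atom table uses the displacement-magnitude
series for this statistic.

## Mode coupling

Because A need not be orthogonal, modes can activate one another.  The
coupling coefficient is taken as the absolute cosine
c_ij = |a_iᵀ a_j| / (‖a_i‖‖a_j‖) ∈ [0, 1] — zero for orthogonal
modes, one for parallel.  "Commonly activated" atoms for a mode pair
are those whose per-atom displacement norm exceeds the 90th percentile
within both mixing columns.  Both the cosine form and the percentile
threshold are this package's conventions; other interaction-strength
definitions are possible.

## Numerical choices

- Superposition: each frame is centred and Kabsch-rotated (proper
  rotations only, so mirror images retain a residual) onto an
  iteratively refined mean; the initial reference is the raw mean
  (making already-superposed input an exact fixed point), falling back
  to frame 0 when rotational smearing degenerates it.  Convergence at
  mean shift < 1e-9 Å RMSD or 50 iterations.
- Jacobi stopping: all rotation sines below θ_min = 1e-2/√T (the
  statistical resolution of sample cumulants — tighter thresholds only
  chase sampling noise), at most 200 sweeps; the objective is
  monotonically non-increasing and its per-sweep history is returned.
- Cumulant sets: the full m(m+1)/2 parallel set is used up to m = 40
  whitened dimensions; above that, memory scales as m⁴ and the set is
  replaced by the m most significant eigenmatrices of the stacked
  m² × m² cumulant (eigenvalue-scaled).
- Mixture fits: covariance regularization 1e-6·trace/d on the
  diagonal, EM tolerance 1e-7, max 500 iterations, all seeds explicit.
- Eigenvector and mode signs fixed by the largest-magnitude component;
  variance-target selection takes the smallest m reaching the target.
- Indexing is 0-based internally; residue selections are 1-based as in
  PDB files; all coordinates are in Å.  Frames are equally weighted;
  no time ordering is used.  Multiple input trajectories are
  concatenated in argument order before analysis.

## Synthetic data

The generators exist so that every stage has planted ground truth:

- **Mixed non-Gaussian sources**: unit-variance Gaussian, Laplace
  (kurtosis 6), uniform (1.8) and bimodal (equal mixture of
  N(±offset, sd²), standardized) sources mixed by a random square
  matrix rejected until its condition number is ≤ 10 — non-orthogonal
  but well-posed.  Recovery is scored by the Amari index of
  A_est⁺ A_true (0 = perfect up to permutation/scale/sign).
- **Toy polymer ensembles**: an ideal helix of beads (rise 1.5 Å,
  100° twist — cosmetic, so the PDB output is viewable) displaced into
  planted wells chosen per frame by weight, with 1-D Gaussian jitter
  along each well direction, optional Gaussian collective modes
  (random directions) emulating the harmonic collective fluctuations
  that dominate real protein spectra, and isotropic Cartesian noise.
  Planted per-frame energy is the well's level plus Gaussian noise
  (sd 0.25).  All planted directions are orthogonalised against the
  rigid-body subspace so superposition does not distort the planted
  mixing.
- Two canonical study conditions are frozen as functions:
  `nested_substates` (4000 frames, 40 beads; a 3 Å major split whose
  larger branch hides a 1.2 Å sub-split beneath two 2.2 Å collective
  modes — visible only on re-decomposition, i.e. a genuine two-level
  landscape) and `anharmonic_energy_wells` (three wells of distinct
  energy along directions with cosine 0.4, jitter 1.2 Å, collective
  modes 2.3 Å).  The latter is built so that variance ranking
  misorders the landscape: non-orthogonal mixing pushes one covariance
  eigenvalue above and one below the planted source variances and the
  collective Gaussian modes sit in between, so a top-3 variance
  (quasi-harmonic) projection drops the minor sub-state direction
  while the top-3 amplitude (anharmonic) projection retains it.  This
  is the mechanism by which the anharmonic clustering achieves lower
  within-cluster energy variance than the harmonic baseline.
- **Umbrella-window emulator**: a bead chain built in internal
  coordinates whose central dihedral is restrained per window with
  harmonic jitter (sd 2°), swept from trans (180°) to cis (0°) in 5°
  decrements with 500 frames per window by default — 37 windows,
  18,500 conformations.

What the generators do **not** emulate: force-field energetics (the
planted energy is a label, not a potential), kinetics or time
correlation, solvent, anisotropic per-well covariance beyond the 1-D
jitter, and the slow conformational exchange that makes real sub-state
populations hard to converge.  Passing tests therefore demonstrate
correctness of the statistical machinery and its behaviour under the
planted conditions, not convergence properties on real trajectories.

## Problem sizes

Tests and the acceptance script run analytic-moment checks at 10⁶
samples, source-recovery benchmarks at 10⁵ samples with 4 sources
(10 seeds), and ensemble studies at 4000 frames × 120 coordinates
(3 seeds for the nested hierarchy, 10 for the homogeneity comparison);
these sizes give sampling error comfortably below every tested margin.

## Known limitations

- The linear model ignores nonlinear couplings between fluctuations;
  strongly curved valleys are represented only piecewise through the
  hierarchy.
- JADE's optimum for *dependent* non-Gaussian sources (e.g. several
  wells sharing a plane) may mix planted directions; the sub-state
  clustering is robust to this (the projection still separates wells)
  but individual modes need not align with individual planted axes.
- Amplitude ordering follows total variance per mode, so a weakly
  populated but functionally important direction can rank below large
  harmonic motions; the hierarchy's per-level re-decomposition is the
  mitigation.
- BIC-based k selection distinguishes wells with different jitter
  anisotropy as separate components; reproducing a fixed published
  cluster count requires the explicit k override.
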