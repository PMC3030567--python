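"""Fourth-order cumulants, joint diagonalization and anharmonic modes."""
import warnings

import numpy as np
import pytest

from qaa.anharmonicity import kurtosis
from qaa.ensembles import DeviationMatrix
from qaa.jade import (
    anharmonic_basis,
    commonly_activated_atoms,
    coupling_matrix,
    cumulant_matrix_set,
    fourth_cross_cumulant,
    joint_diagonalize,
    project_anharmonic,
    qaa_decompose,
)
from qaa.qha import covariance_matrix, harmonic_basis, whiten_project
from qaa.synthetic import SourceSpec, Well, amari_index, make_ica_dataset, make_toy_ensemble


def _whitened(X):
    dev = DeviationMatrix.from_matrix(X)
    hb = harmonic_basis(covariance_matrix(dev), mode_count=X.shape[1])
    return whiten_project(dev, hb)


class TestFourthCrossCumulant:
    def test_gaussian_cumulants_vanish(self):
        Z = _whitened(np.random.default_rng(0).standard_normal((10**6, 3)))
        for idx in [(0, 0, 0, 0), (0, 1, 0, 1), (0, 1, 2, 0)]:
            assert fourth_cross_cumulant(Z, *idx) == pytest.approx(0.0, abs=0.01)

    def test_laplace_auto_cumulant(self):
        x = np.random.default_rng(1).laplace(size=10**6) / np.sqrt(2)
        Z = _whitened(x[:, None])
        assert fourth_cross_cumulant(Z, 0, 0, 0, 0) == pytest.approx(3.0, abs=0.1)

    def test_permutation_invariance_exact(self):
        Z = _whitened(np.random.default_rng(2).standard_normal((500, 4)))
        base = fourth_cross_cumulant(Z, 0, 1, 2, 3)
        for perm in [(1, 0, 2, 3), (2, 3, 0, 1), (3, 1, 2, 0), (0, 2, 1, 3)]:
            assert fourth_cross_cumulant(Z, *perm) == pytest.approx(base, abs=1e-12)

    def test_index_out_of_range(self):
        Z = _whitened(np.random.default_rng(3).standard_normal((100, 2)))
        with pytest.raises(IndexError):
            fourth_cross_cumulant(Z, 0, 0, 0, 5)


class TestCumulantMatrixSet:
    def test_matches_naive_oracle(self):
        Z = _whitened(np.random.default_rng(4).standard_normal((500, 3)) * [1, 2, 3])
        cm = cumulant_matrix_set(Z)
        for (i, j), Q in zip(cm.pairs, cm.matrices):
            for k in range(3):
                for l in range(3):
                    assert Q[k, l] == pytest.approx(
                        fourth_cross_cumulant(Z, i, j, k, l), abs=1e-12
                    )

    def test_gaussian_entries_within_noise(self):
        # per-entry estimator sd is O(sqrt(24/T)); the RMS over all
        # entries must sit at that scale and the max within ~4 sd
        T = 20000
        Z = _whitened(np.random.default_rng(5).standard_normal((T, 4)))
        cm = cumulant_matrix_set(Z)
        assert np.sqrt(np.mean(cm.matrices**2)) < 5 / np.sqrt(T)
        assert np.abs(cm.matrices).max() < 4 * np.sqrt(24 / T)

    def test_independent_laplace_diagonal_structure(self):
        # symmetric whitening (C^-1/2) keeps the source alignment; PCA
        # whitening would rotate arbitrarily in the near-isotropic case
        T = 10**5
        rng = np.random.default_rng(6)
        X = rng.laplace(size=(T, 3))
        X -= X.mean(0)
        C = X.T @ X / T
        evals, evecs = np.linalg.eigh(C)
        Z = X @ (evecs / np.sqrt(evals)) @ evecs.T
        cm = cumulant_matrix_set(Z)
        for (i, j), Q in zip(cm.pairs, cm.matrices):
            if i == j:
                expected = np.zeros((3, 3))
                expected[i, i] = 3.0
                # Laplace eighth moments make the estimator sd ~
                # sqrt(2520/T) ~ 0.16; allow a few sd per entry
                np.testing.assert_allclose(Q, expected, atol=0.6)

    def test_unwhitened_input_reports_deviation(self):
        X = np.random.default_rng(7).standard_normal((500, 3)) * [1, 5, 1]
        with pytest.raises(ValueError, match="not whitened"):
            cumulant_matrix_set(X - X.mean(0))

    def test_matrix_count_and_symmetry(self):
        Z = _whitened(np.random.default_rng(8).standard_normal((400, 4)))
        cm = cumulant_matrix_set(Z)
        assert len(cm.matrices) == 4 * 5 // 2
        assert np.abs(cm.matrices - cm.matrices.transpose(0, 2, 1)).max() < 1e-10

    def test_truncated_set_preserves_jade_rotation(self):
        data, truth = make_ica_dataset(
            [SourceSpec("uniform", 2), SourceSpec("laplace")], T=20000, seed=9
        )
        Z = _whitened(data)
        full = joint_diagonalize(cumulant_matrix_set(Z, truncate=False))
        trunc = joint_diagonalize(cumulant_matrix_set(Z, truncate=True))
        # rotations agree up to permutation/sign: compare via Amari index
        assert amari_index(full.rotation, trunc.rotation) < 0.05


class TestJointDiagonalize:
    def test_already_diagonal_is_fixed_point(self):
        rng = np.random.default_rng(10)
        mats = np.array([np.diag(rng.normal(0, 1, 4) + np.arange(2, 6)) for _ in range(5)])
        from qaa.jade import CumulantMatrixSet

        cms = CumulantMatrixSet(
            matrices=mats, pairs=[(i, i) for i in range(5)],
            weights=np.ones(5), sample_count=1000,
        )
        res = joint_diagonalize(cms)
        P = np.abs(res.rotation)
        # V is a signed permutation; residual unchanged
        assert np.allclose(P @ P.T, np.eye(4), atol=1e-8)
        assert res.residual == pytest.approx(res.residual_history[0], rel=1e-6)

    def test_single_matrix_reduces_to_eigendecomposition(self):
        rng = np.random.default_rng(11)
        S = rng.standard_normal((5, 5))
        S = S + S.T
        from qaa.jade import CumulantMatrixSet

        cms = CumulantMatrixSet(
            matrices=S[None], pairs=[(0, 0)], weights=np.ones(1), sample_count=10**6
        )
        res = joint_diagonalize(cms, theta_min=1e-12, max_sweeps=500)
        D = res.rotation.T @ S @ res.rotation
        off = D - np.diag(np.diag(D))
        assert np.abs(off).max() < 1e-8

    def test_objective_monotone_nonincreasing(self):
        data, _ = make_ica_dataset(
            [SourceSpec("uniform", 2), SourceSpec("bimodal")], T=5000, seed=12
        )
        Z = _whitened(data)
        res = joint_diagonalize(cumulant_matrix_set(Z))
        hist = np.array(res.residual_history)
        assert np.all(np.diff(hist) <= 1e-10)

    def test_gaussian_only_warns_unidentifiable(self):
        Z = _whitened(np.random.default_rng(13).standard_normal((5000, 3)))
        with pytest.warns(RuntimeWarning, match="unidentifiable"):
            joint_diagonalize(cumulant_matrix_set(Z))

    def test_recovered_sources_less_cross_cumulant_than_input(self):
        data, _ = make_ica_dataset(
            [SourceSpec("laplace", 2), SourceSpec("uniform")], T=20000, seed=14
        )
        Z = _whitened(data)
        cm = cumulant_matrix_set(Z)
        res = joint_diagonalize(cm)
        assert res.residual < res.residual_history[0]


class TestAnharmonicBasis:
    def test_identity_rotation_reproduces_harmonic_basis(self, rng):
        from .conftest import random_deviations

        dev = random_deviations(rng, T=300, n_coords=6)
        hb = harmonic_basis(covariance_matrix(dev), mode_count=4)
        ab = anharmonic_basis(dev, hb, np.eye(4))
        # columns are sqrt(lambda)-scaled eigenvectors, amplitude-ordered
        np.testing.assert_allclose(
            np.abs(ab.mixing),
            np.abs(hb.eigenvectors * np.sqrt(hb.eigenvalues)),
            atol=1e-10,
        )

    def test_demixing_times_mixing_is_identity(self):
        data, _ = make_ica_dataset(
            [SourceSpec("uniform", 2), SourceSpec("laplace", 2)], T=20000, seed=15
        )
        dev = DeviationMatrix.from_matrix(data)
        ab = qaa_decompose(dev, mode_count=4)
        np.testing.assert_allclose(ab.demixing @ ab.mixing, np.eye(4), atol=1e-6)

    def test_source_covariance_identity_and_amplitudes_sorted(self):
        data, _ = make_ica_dataset(
            [SourceSpec("bimodal", 2), SourceSpec("uniform")], T=20000, seed=16
        )
        dev = DeviationMatrix.from_matrix(data)
        ab = qaa_decompose(dev, mode_count=3)
        S = project_anharmonic(dev, ab)
        cov = S.T @ S / S.shape[0]
        assert np.abs(cov - np.eye(3)).max() < 1e-6
        assert np.all(np.diff(ab.amplitudes) <= 1e-12)

    def test_planted_mixing_recovered(self):
        indices = []
        for seed in range(5):
            data, truth = make_ica_dataset(
                [SourceSpec("laplace", 2), SourceSpec("uniform"), SourceSpec("bimodal")],
                T=50000, seed=seed,
            )
            ab = qaa_decompose(DeviationMatrix.from_matrix(data), mode_count=4)
            indices.append(amari_index(truth.mixing_true, ab.mixing))
        assert np.median(indices) < 0.05

    def test_prefix_projection(self):
        data, _ = make_ica_dataset([SourceSpec("uniform", 3)], T=5000, seed=17)
        dev = DeviationMatrix.from_matrix(data)
        ab = qaa_decompose(dev, mode_count=3)
        full = project_anharmonic(dev, ab)
        np.testing.assert_allclose(project_anharmonic(dev, ab, 2), full[:, :2])
        with pytest.raises(ValueError):
            project_anharmonic(dev, ab, 9)

    def test_two_well_ensemble_separates_along_one_mode(self, rng):
        from sklearn.metrics import silhouette_score

        direction = rng.standard_normal(30)
        wells = [
            Well(direction=direction, magnitude=2.0, energy=0.0, weight=0.5),
            Well(direction=-direction, magnitude=2.0, energy=1.0, weight=0.5),
        ]
        ens, truth = make_toy_ensemble(10, wells, noise_sd=0.1, T=2000, seed=18,
                                       jitter_sd=0.2)
        from qaa.ensembles import compute_deviations, superpose_ensemble

        dev = compute_deviations(superpose_ensemble(ens))
        ab = qaa_decompose(dev, variance_target=0.95, max_modes=10)
        S = project_anharmonic(dev, ab, 1)
        assert silhouette_score(S, truth.source_labels) > 0.5


class TestCoupling:
    def test_cosine_geometry(self):
        hb = harmonic_basis(np.diag([1.0, 1.0, 1.0]), mode_count=3)
        ab = anharmonic_basis(np.zeros((2, 3)), hb, np.eye(3))
        # orthogonal columns -> zero off-diagonals
        c = coupling_matrix(ab).c
        np.testing.assert_allclose(c, np.eye(3), atol=1e-10)

    def test_sixty_degree_columns(self):
        ab = type("S", (), {})()
        ab.mixing = np.array([[1.0, 0.5], [0.0, np.sqrt(3) / 2]])
        c = coupling_matrix(ab).c
        assert c[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert c[0, 0] == 1.0

    def test_identical_columns_give_one(self):
        ab = type("S", (), {})()
        a = np.array([1.0, 2.0, 3.0])
        ab.mixing = np.column_stack([a, a])
        assert coupling_matrix(ab).c[0, 1] == pytest.approx(1.0)

    def test_commonly_activated_atoms(self):
        ab = type("S", (), {})()
        A = np.zeros((30, 2))  # 10 atoms
        A[0:3, 0] = 5.0   # atom 0 strong in mode 0
        A[0:3, 1] = 5.0   # and in mode 1
        A[3:6, 0] = 4.0   # atom 1 strong only in mode 0
        A[27:30, 1] = 4.0  # atom 9 strong only in mode 1
        A += 0.01
        ab.mixing = A
        atoms = commonly_activated_atoms(ab, 0, 1, quantile=0.8)
        assert 0 in atoms and 1 not in atoms and 9 not in atoms
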