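import numpy as np
import pytest

from qaa.ensembles import (
    ConformationalEnsemble,
    DeviationMatrix,
    compute_deviations,
    superpose_ensemble,
    _default_meta,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_ensemble(rng):
    """Random 20-frame, 6-atom ensemble (already internally consistent)."""
    base = rng.normal(0, 3, (6, 3))
    coords = base[None] + rng.normal(0, 0.4, (20, 6, 3))
    return ConformationalEnsemble(coords=coords, atom_meta=_default_meta(6))


@pytest.fixture
def small_deviations(small_ensemble):
    return compute_deviations(superpose_ensemble(small_ensemble))


def random_deviations(rng, T=300, n_coords=9):
    """Anisotropic random deviation matrix for whitening tests."""
    A = rng.standard_normal((n_coords, n_coords))
    X = rng.standard_normal((T, n_coords)) @ A
    return DeviationMatrix.from_matrix(X)


def pdb_fixture(tmp_path, coords, name="ens.pdb"):
    from qaa.ensembles import write_ensemble_pdb

    path = tmp_path / name
    write_ensemble_pdb(np.asarray(coords), path)
    return path
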