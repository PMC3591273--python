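import numpy as np
import pytest

from pocketeer import benchmark
from pocketeer.fixtures import DEFAULT_SUITE, FixtureSpec, make_fixture
from pocketeer.pocketgrid import PocketParams

ACCEPTANCE_SEED = 20230307


@pytest.fixture(scope="session")
def suite():
    """All canonical fixtures as {kind: (structure, truth)}."""
    return {spec.kind: make_fixture(spec) for spec in DEFAULT_SUITE}


@pytest.fixture(scope="session")
def flask_fixture():
    return make_fixture(FixtureSpec("flask", lattice=1.4))


@pytest.fixture(scope="session")
def slab_fixture():
    return make_fixture(FixtureSpec("slab"))


@pytest.fixture(scope="session")
def mini_protein():
    return make_fixture(FixtureSpec("mini_protein"))


@pytest.fixture(scope="session")
def hinge_system():
    return benchmark.hinge_system()


@pytest.fixture(scope="session")
def strained_hinge():
    return benchmark.strained_hinge_system()


@pytest.fixture(scope="session")
def hinge_quadrature(hinge_system):
    return benchmark.hinge_quadrature(hinge_system, step_deg=1.0)


@pytest.fixture(scope="session")
def strained_quadrature(strained_hinge):
    return benchmark.hinge_quadrature(strained_hinge, step_deg=1.0)


@pytest.fixture(scope="session")
def hinge_ensembles(hinge_system, strained_hinge):
    """The three 200-run benchmark ensembles (shared by the acceptance
    criteria tests; this is the expensive part of the suite)."""
    return {
        "unbiased": benchmark.run_hinge_ensemble(hinge_system, "unbiased", seed=ACCEPTANCE_SEED),
        "moderate": benchmark.run_hinge_ensemble(hinge_system, "moderate", seed=ACCEPTANCE_SEED),
        "strong_strained": benchmark.run_hinge_ensemble(
            strained_hinge, "strong", seed=ACCEPTANCE_SEED
        ),
    }


@pytest.fixture()
def default_params():
    return PocketParams()


def random_cloud(seed: int, n_atoms: int = 10):
    """Seeded random atom cloud with per-atom residues; target is the
    atom closest to the centroid."""
    from pocketeer.structio import Atom, ResidueSelector, Structure, assign_radii

    rng = np.random.default_rng(seed)
    xyz = rng.normal(scale=2.5, size=(n_atoms, 3))
    atoms = [
        Atom(
            serial=i + 1,
            name="A001",
            element="C",
            residue_name="FXB",
            chain_id="A",
            residue_number=i + 1,
            coords=xyz[i],
        )
        for i in range(n_atoms)
    ]
    structure = assign_radii(Structure(atoms=atoms))
    centroid = xyz.mean(axis=0)
    target_i = int(np.argmin(((xyz - centroid) ** 2).sum(axis=1)))
    return structure, ResidueSelector("A", target_i + 1)
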