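import numpy as np
import pytest

from chromoscape.structures import Structure3D, TracedEnsemble
from chromoscape.units import UNIT_NM, UNIT_REDUCED


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_structure(rng, n_loci=30, scale=400.0, units=UNIT_NM,
                     missing=0.0, structure_id="s"):
    coords = rng.normal(scale=scale, size=(n_loci, 3))
    if missing:
        coords[rng.random(n_loci) < missing] = np.nan
    return Structure3D(coords=coords, units=units, structure_id=structure_id)


@pytest.fixture
def small_ensemble(rng):
    """Five random nm-unit structures of 30 loci, some with missing loci."""
    structures = [random_structure(rng, missing=0.1 if i % 2 else 0.0,
                                   structure_id=f"s{i}") for i in range(5)]
    return TracedEnsemble(structures=structures, chrom="chr21",
                          resolution=50_000)


@pytest.fixture(scope="session")
def reduced_frame():
    rng = np.random.default_rng(7)
    return Structure3D(coords=rng.normal(scale=2.0, size=(25, 3)),
                       units=UNIT_REDUCED, structure_id="frame0")


@pytest.fixture(scope="session")
def two_domain_result():
    """Scaled two-domain dumbbell study (shared: expensive)."""
    from chromoscape.studies import run_two_domain_study
    return run_two_domain_study(seed=1)


@pytest.fixture(scope="session")
def phase_separated_ensemble():
    """Two-type confined chain with strongest B-B attraction (shared)."""
    from chromoscape.dynamics import SimulationSchedule, simulate
    from chromoscape.michrom import MiChroMParams, toy_alpha
    labels = np.array((["A1"] * 10 + ["B3"] * 10) * 5, dtype=object)
    params = MiChroMParams(alpha=toy_alpha(b_b=-0.40))
    sched = SimulationSchedule(anneal_steps=30_000, prod_steps=90_000,
                               save_every=3_000, n_replicates=4, seed=2)
    ens = simulate(labels, None, params, sched, compute_energies=False)
    return labels, ens
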