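import numpy as np
import pytest

import cgfibril as cf


@pytest.fixture(scope="session")
def nonbonded():
    return cf.NonbondedTable.martini_cellulose()


@pytest.fixture(scope="session")
def chain20():
    """Typed ideal 20-residue Ialpha chain with its bond terms."""
    model = cf.assign_bead_types(cf.build_chain(20, "Ialpha"))
    return model, cf.make_bond_terms(model)


@pytest.fixture(scope="session")
def chain20_traj(chain20, nonbonded):
    """Thermostatted 300 K run of the 20-residue chain (shared, ~1 ns)."""
    model, bonds = chain20
    config = cf.EngineConfig(seed=42)
    relaxed, _ = cf.minimize(model, bonds, nonbonded, config,
                             max_steps=2000, fmax=5.0)
    traj = cf.run_dynamics(relaxed, bonds, nonbonded, config,
                           n_steps=50_000, report_every=200)
    return model, bonds, relaxed, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(20220203)
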