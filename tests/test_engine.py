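"""Potentials, forces, minimization and dynamics contracts."""

import numpy as np
import pytest

import cgfibril as cf
from cgfibril.engine import System
from cgfibril.errors import InvalidArgumentError, InvalidModelError, NumericalFailure
from cgfibril.params import BONDED_PARAMS, KB


def test_bond_energy_closed_forms():
    v, _ = cf.bond_energy(2.88, 2.88, 30000.0)
    assert v == 0.0
    v, _ = cf.bond_energy(2.98, 2.88, 30000.0)       # 0.01 nm stretch
    assert v == pytest.approx(0.5 * 30000 * 0.01**2)  # 1.5 kJ/mol
    v, _ = cf.bond_energy(7.42, 6.42, 2500.0)         # 0.1 nm stretch, soft
    assert v == pytest.approx(12.5)


def test_lj_energy_closed_forms():
    sigma, eps = cf.nonbonded_lookup("SP6", "SP6")
    assert cf.lj_energy(sigma, sigma, eps, cutoff=None) == pytest.approx(0.0)
    rmin = 2 ** (1 / 6) * sigma
    assert cf.lj_energy(rmin, sigma, eps, cutoff=None) == pytest.approx(-eps)
    assert cf.lj_energy(12.0, sigma, eps, cutoff=1.1) == 0.0  # beyond cutoff


def test_lj_potential_shift_continuous_at_cutoff():
    sigma, eps = cf.nonbonded_lookup("SP6", "TC1")
    just_in = cf.lj_energy(10.999, sigma, eps, cutoff=1.1, shift=True)
    assert abs(just_in) < 1e-3


def _random_system(rng, n_residues=3):
    model = cf.assign_bead_types(cf.build_chain(n_residues, "Ibeta"))
    jittered = model.with_positions(
        model.positions + rng.normal(0, 0.3, model.positions.shape))
    bonds = cf.make_bond_terms(model)
    return jittered, bonds


def test_forces_match_finite_differences(rng, nonbonded):
    """Analytic forces are the exact negative gradient (central differences)."""
    model, bonds = _random_system(rng, n_residues=4)
    config = cf.EngineConfig()
    e0, forces, _ = cf.total_energy_forces(model, bonds, nonbonded, config)
    h = 1e-5  # nm
    sys_ = System(model, bonds, nonbonded, config)
    sys_._build_pairs()
    check = rng.choice(model.n_beads, size=6, replace=False)
    for i in check:
        for d in range(3):
            saved = sys_.pos[i, d]
            sys_.pos[i, d] = saved + h
            ep = sys_.energy_forces()[0]
            sys_.pos[i, d] = saved - h
            em = sys_.energy_forces()[0]
            sys_.pos[i, d] = saved
            f_num = -(ep - em) / (2 * h)
            assert forces[i, d] == pytest.approx(f_num, rel=1e-6, abs=1e-5)


def test_ideal_chain_has_zero_bond_energy(nonbonded):
    model = cf.assign_bead_types(cf.build_chain(6, "Ialpha"))
    bonds = cf.make_bond_terms(model)
    _, _, parts = cf.total_energy_forces(model, bonds, nonbonded)
    assert parts["bond"] == pytest.approx(0.0, abs=1e-12)


def test_lj_minimum_two_beads(nonbonded):
    """Two SP6 beads at the LJ minimum distance: E = -epsilon (large cutoff)."""
    sigma, eps = nonbonded.lookup("SP6", "SP6")
    rmin = 2 ** (1 / 6) * sigma
    model = cf.FibrilModel(
        "Ibeta",
        positions=np.array([[0.0, 0, 0], [rmin, 0, 0],
                            [0, 0, 60.0], [40.0, 0, 60.0]]),
        chain_ids=[0, 0, 0, 0], residue_indices=[0, 0, 0, 0],
        site_labels=["CG1", "CG2", "CG3", "CG4"],
        box_vectors=np.eye(3) * 200)
    # only the two SP6 beads interact: all other pairs lie beyond the cutoff
    model = cf.assign_bead_types(model)
    config = cf.EngineConfig(lj_cutoff=1.5)
    e, _, parts = cf.total_energy_forces(model, bonds=[], nonbonded=nonbonded,
                                         config=config)
    assert parts["lj"] == pytest.approx(-eps, abs=0.05)


def test_coincident_beads_rejected(nonbonded):
    model = cf.assign_bead_types(cf.build_chain(2, "Ibeta"))
    pos = model.positions.copy()
    pos[1] = pos[0]
    with pytest.raises(InvalidModelError):
        cf.total_energy_forces(model.with_positions(pos),
                               cf.make_bond_terms(model), nonbonded)


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def test_minimize_two_bead_bond_reaches_r0(nonbonded):
    """1-D analytic solution: a lone harmonic bond relaxes to r = r0."""
    model = cf.assign_bead_types(cf.build_chain(1, "Ibeta"))
    bonds = [b for b in cf.make_bond_terms(model)]
    start = model.positions.copy()
    start[0] += [0.9, 0.3, -0.4]
    relaxed, info = cf.minimize(model.with_positions(start), bonds, nonbonded,
                                max_steps=5000, fmax=1e-3)
    for b in bonds:
        d = np.linalg.norm(relaxed.positions[b.i] - relaxed.positions[b.j])
        assert d == pytest.approx(b.r0, abs=1e-3)


def test_minimize_lowers_energy_of_perturbed_chain(nonbonded):
    model = cf.assign_bead_types(cf.build_chain(5, "Ibeta"))
    bonds = cf.make_bond_terms(model)
    pos = model.positions.copy()
    pos[7] += [0.5, 0.0, 0.0]
    perturbed = model.with_positions(pos)
    e0, _, parts0 = cf.total_energy_forces(perturbed, bonds, nonbonded)
    relaxed, info = cf.minimize(perturbed, bonds, nonbonded, max_steps=300)
    assert info["energy"] < e0


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def test_zero_temperature_single_residue_is_static(nonbonded):
    """At 0 K with zero forces (all pairs bonded), nothing moves."""
    model = cf.assign_bead_types(cf.build_chain(1, "Ibeta"))
    bonds = cf.make_bond_terms(model)
    config = cf.EngineConfig(temperature=0.0, seed=1)
    traj = cf.run_dynamics(model, bonds, nonbonded, config,
                           n_steps=500, report_every=100)
    np.testing.assert_allclose(traj.coordinates[-1], traj.coordinates[0],
                               atol=1e-10)


def test_same_seed_bitwise_identical(nonbonded, chain20):
    model, bonds = chain20
    config = cf.EngineConfig(seed=99)
    t1 = cf.run_dynamics(model, bonds, nonbonded, config, 300, report_every=50)
    t2 = cf.run_dynamics(model, bonds, nonbonded, config, 300, report_every=50)
    assert (t1.coordinates == t2.coordinates).all()
    t3 = cf.run_dynamics(model, bonds, nonbonded,
                         cf.EngineConfig(seed=100), 300, report_every=50)
    assert not (t1.coordinates[-1] == t3.coordinates[-1]).all()


def test_single_bond_equipartition(nonbonded):
    """<1/2 k (r-r0)^2> ~ 1/2 kB T for one stiff bond (radial mode)."""
    model = cf.FibrilModel(
        "Ibeta",
        positions=np.array([[0.0, 0, 0], [2.88, 0, 0]]),
        chain_ids=[0, 0], residue_indices=[0, 0],
        site_labels=["CG1", "CG2"], box_vectors=np.eye(3) * 50)
    model = cf.assign_bead_types(model)
    bonds = [cf.BondTerm(0, 1, 2.88, 30000.0, "intra", "O2-O3")]
    config = cf.EngineConfig(temperature=300.0, seed=3)
    traj = cf.run_dynamics(model, bonds, nonbonded, config,
                           n_steps=60_000, report_every=20)
    prod = traj.sliced(500)
    d = np.linalg.norm(prod.coordinates[:, 0] - prod.coordinates[:, 1], axis=1)
    v = 0.5 * 30000.0 * ((d - 2.88) * 0.1) ** 2
    assert v.mean() == pytest.approx(0.5 * KB * 300.0, rel=0.2)


def test_temperature_control(chain20_traj):
    """Time-average kinetic temperature within 3% of the 300 K target."""
    _, _, _, traj = chain20_traj
    temps = np.array([rec["temperature"] for rec in traj.metadata["log"][50:]])
    assert temps.mean() == pytest.approx(300.0, rel=0.03)


def test_v_rescale_thermostat_controls_temperature(chain20, nonbonded):
    model, bonds = chain20
    config = cf.EngineConfig(thermostat="v_rescale", tau_t=0.5, seed=5)
    traj = cf.run_dynamics(model, bonds, nonbonded, config,
                           n_steps=20_000, report_every=50)
    temps = np.array([rec["temperature"] for rec in traj.metadata["log"][100:]])
    assert temps.mean() == pytest.approx(300.0, rel=0.05)


def test_nve_energy_conservation(chain20, nonbonded):
    """Thermostat off: the velocity-Verlet integrator conserves energy.

    Checked at a timestep where the stiffest elastic-network mode is well
    inside the Verlet stability region (omega*dt ~ 0.8); at the 0.02 ps
    production timestep those modes sit at omega*dt ~ 1.6 and shadow-energy
    diffusion dominates (see the methods note).
    """
    model, bonds = chain20
    relaxed, _ = cf.minimize(model, bonds, nonbonded, max_steps=500)
    warm = cf.run_dynamics(relaxed, bonds, nonbonded,
                           cf.EngineConfig(seed=8), 2_000, report_every=2_000)
    start = relaxed.with_positions(warm.coordinates[-1])
    config = cf.EngineConfig(thermostat="none", seed=8, timestep=0.01)
    traj = cf.run_dynamics(start, bonds, nonbonded, config,
                           n_steps=100_000, report_every=100)
    log = traj.metadata["log"][1:]
    total = np.array([r["potential"] + r["kinetic_on_step"] for r in log])
    kinetic = np.array([r["kinetic_on_step"] for r in log])
    head = total[: len(total) // 5].mean()
    tail = total[-(len(total) // 5):].mean()
    assert abs(tail - head) / kinetic.mean() < 1e-3


def test_stiff_bond_means_stay_at_r0(chain20_traj):
    """Mechanism behind the tabulated CG distance means: stiff bonds keep r0."""
    model, bonds, relaxed, traj = chain20_traj
    prod = traj.sliced(traj.n_frames // 2)
    for cls, lbl in [("intra", "O2-O3"), ("intra", "C6-O6"),
                     ("first", "O3-O3"), ("second", "C6-C6")]:
        st = cf.pair_distance_stats(prod, model, lbl, cls)
        r0 = BONDED_PARAMS[(cls, lbl)][0]
        assert st.mean == pytest.approx(r0, abs=0.05)


def test_thermal_stability_300K_vs_400K(chain20, nonbonded):
    """Both 300 K and 400 K runs stay intact; RMSD grows with temperature."""
    model, bonds = chain20
    relaxed, _ = cf.minimize(model, bonds, nonbonded, max_steps=1000)
    results = {}
    for temp in (300.0, 400.0):
        config = cf.EngineConfig(temperature=temp, seed=13)
        traj = cf.run_dynamics(relaxed, bonds, nonbonded, config,
                               n_steps=150_000, report_every=300)
        prod = traj.sliced(traj.n_frames // 3)
        mean, _, _ = cf.traj_mean_rmsd(prod, reference=prod.frame(0))
        results[temp] = mean
    assert results[400.0] >= results[300.0]
    assert results[400.0] < 10.0  # bonded network intact, no melting


def test_instability_raises_named_step(chain20, nonbonded):
    model, bonds = chain20
    config = cf.EngineConfig(timestep=5.0, seed=1)  # far beyond stability
    with pytest.raises(NumericalFailure, match="step"):
        cf.run_dynamics(model, bonds, nonbonded, config, 2_000, report_every=50)


def test_bad_config_rejected():
    with pytest.raises(InvalidArgumentError):
        cf.EngineConfig(timestep=-1.0)
    with pytest.raises(InvalidArgumentError):
        cf.EngineConfig(temperature=-5.0)
    with pytest.raises(InvalidArgumentError):
        cf.EngineConfig(thermostat="nose")
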