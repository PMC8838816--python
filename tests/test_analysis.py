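"""RMSD, twist dihedral and pair-distance statistics.

Independent oracles: mdtraj for superposed RMSD and dihedrals, an explicit
rotation-matrix dihedral construction, and brute-force checks of metric
properties.
"""

import numpy as np
import pytest

import cgfibril as cf
from cgfibril.errors import InvalidArgumentError, UndefinedDihedralError


def _traj(frames, box=None):
    frames = np.asarray(frames, dtype=float)
    return cf.Trajectory(times=np.arange(len(frames), dtype=float),
                         coordinates=frames,
                         box_vectors=np.eye(3) * 200 if box is None else box)


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------

def test_rmsd_identity_and_rigid_invariance(rng):
    X = rng.normal(size=(10, 3)) * 5
    assert cf.kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-9)
    assert cf.kabsch_rmsd(X, X + np.array([5.0, 5.0, 5.0])) == \
        pytest.approx(0.0, abs=1e-9)
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(4))
    assert cf.kabsch_rmsd(X, R.apply(X) - 3.0) == pytest.approx(0.0, abs=1e-8)


def test_rmsd_raw_square_example():
    """Unit square with one corner lifted 1 Å: raw RMSD = sqrt(1/4) = 0.5."""
    X = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    Y = X.copy()
    Y[2, 2] = 1.0
    assert cf.kabsch_rmsd(X, Y, superpose=False) == pytest.approx(0.5)


def test_superposed_rmsd_vs_rotation_grid():
    """Superposed RMSD equals the brute-force minimum over a rotation grid."""
    from scipy.spatial.transform import Rotation

    X = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    Y = X.copy()
    Y[2, 2] = 1.0
    got = cf.kabsch_rmsd(X, Y, superpose=True)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    best = np.inf
    rng_r = np.random.RandomState(7)
    for _ in range(20000):
        R = Rotation.random(random_state=rng_r)
        d = Xc - R.apply(Yc)
        best = min(best, np.sqrt((d * d).sum() / len(X)))
    assert got <= best + 1e-9
    assert got == pytest.approx(best, abs=5e-3)


def test_superposed_rmsd_matches_mdtraj(rng):
    import mdtraj as md
    from mdtraj.core import element as elem

    X = rng.normal(size=(12, 3)) * 4
    Y = X + rng.normal(size=(12, 3)) * 0.8
    top = md.Topology()
    ch = top.add_chain()
    res = top.add_residue("X", ch)
    for i in range(12):
        top.add_atom(f"A{i}", elem.oxygen, res)
    t = md.Trajectory(np.array([X, Y]) / 10.0, top)
    expected = md.rmsd(t, t, frame=0)[1] * 10.0
    assert cf.kabsch_rmsd(X, Y) == pytest.approx(expected, rel=1e-4)


def test_rmsd_pseudo_metric_on_random_frames(rng):
    frames = rng.normal(size=(4, 8, 3)) * 3
    d = {}
    for i in range(4):
        for j in range(4):
            d[i, j] = cf.kabsch_rmsd(frames[i], frames[j])
    for i in range(4):
        assert d[i, i] == pytest.approx(0.0, abs=1e-9)
        for j in range(4):
            assert d[i, j] == pytest.approx(d[j, i], abs=1e-8)
            for k in range(4):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-8


def test_rmsd_shape_mismatch():
    with pytest.raises(InvalidArgumentError):
        cf.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# trajectory mean RMSD / cross RMSD
# ---------------------------------------------------------------------------

def test_traj_mean_rmsd_identical_frames(rng):
    X = rng.normal(size=(6, 3))
    mean, sd, _ = cf.traj_mean_rmsd(_traj([X, X, X]), reference="last")
    assert mean == pytest.approx(0.0, abs=1e-9)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_traj_mean_rmsd_arithmetic():
    """Frames at raw RMSD 1 and 3 from the reference: mean 2, sd 1."""
    ref = np.zeros((4, 3))
    f1 = ref.copy()
    f1[:, 0] = 1.0   # every atom displaced 1 Å -> RMSD 1
    f2 = ref.copy()
    f2[:, 0] = 3.0
    mean, sd, _ = cf.traj_mean_rmsd(_traj([f1, f2]), reference=ref,
                                    superpose=False)
    assert mean == pytest.approx(2.0)
    assert sd == pytest.approx(1.0)


def test_cross_rmsd_counting_and_identity(rng):
    X = rng.normal(size=(5, 3))
    a = _traj([X])
    mean, sd, n = cf.cross_rmsd(a, a)
    assert mean == pytest.approx(0.0, abs=1e-9) and n == 1
    A = _traj(rng.normal(size=(3, 5, 3)))
    B = _traj(rng.normal(size=(4, 5, 3)))
    _, _, n = cf.cross_rmsd(A, B)
    assert n == 12


def test_cross_rmsd_rigid_rotation_invariance(rng):
    from scipy.spatial.transform import Rotation

    model = cf.build_chain(4, "Ibeta")
    frames = model.positions[None] + rng.normal(size=(3, 16, 3)) * 0.1
    R = Rotation.random(random_state=np.random.RandomState(3))
    rotated = np.array([R.apply(f) + 7.0 for f in frames])
    mean, _, _ = cf.cross_rmsd(_traj(frames), _traj(rotated))
    # every frame pair appears in both trajectories up to the rigid motion
    self_mean, _, _ = cf.cross_rmsd(_traj(frames), _traj(frames))
    assert mean == pytest.approx(self_mean, abs=1e-8)


def test_cross_rmsd_unmappable():
    with pytest.raises(InvalidArgumentError):
        cf.cross_rmsd(_traj(np.zeros((1, 4, 3))), _traj(np.zeros((1, 5, 3))))


# ---------------------------------------------------------------------------
# twist dihedral
# ---------------------------------------------------------------------------

def brute_force_dihedral(p1, p2, p3, p4):
    """Rotation-matrix construction: angle of p4 about the p2-p3 axis.

    Clockwise-positive viewed along p2 -> p3 (the convention in which the
    reference quadruple (0,0,0),(1,0,0),(1,1,0),(1,1,1) scores -90 deg).
    """
    b2 = p3 - p2
    ez = b2 / np.linalg.norm(b2)
    u = p1 - p2
    u = u - (u @ ez) * ez
    v = p4 - p3
    v = v - (v @ ez) * ez
    ex = u / np.linalg.norm(u)
    ey = np.cross(ez, ex)
    # counterclockwise angle, negated for the clockwise-positive convention
    return float(-np.degrees(np.arctan2(v @ ey, v @ ex)))


def test_twist_angle_examples():
    assert cf.twist_angle([0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]) == \
        pytest.approx(0.0, abs=1e-12)
    assert cf.twist_angle([0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]) == \
        pytest.approx(-90.0)


def test_twist_angle_reversal_symmetry(rng):
    for _ in range(50):
        p = rng.normal(size=(4, 3)) * 3
        try:
            a = cf.twist_angle(*p)
            b = cf.twist_angle(*p[::-1])
        except UndefinedDihedralError:
            continue
        assert abs(a) == pytest.approx(abs(b), abs=1e-9)


def test_twist_angle_against_brute_force_oracle(rng):
    for _ in range(1000):
        p = rng.normal(size=(4, 3)) * 5
        try:
            got = cf.twist_angle(*p)
        except UndefinedDihedralError:
            continue
        assert got == pytest.approx(brute_force_dihedral(*p), abs=1e-9)


def test_twist_angle_matches_mdtraj(rng):
    import mdtraj as md
    from mdtraj.core import element as elem

    quads = rng.normal(size=(64, 4, 3)) * 4
    top = md.Topology()
    ch = top.add_chain()
    res = top.add_residue("X", ch)
    for i in range(4):
        top.add_atom(f"A{i}", elem.oxygen, res)
    t = md.Trajectory(quads / 10.0, top)
    # mdtraj's sign convention is opposite to the one used here (ours puts
    # the reference quadruple at -90 deg); magnitudes agree exactly
    expected = -np.degrees(
        md.compute_dihedrals(t, [[0, 1, 2, 3]], periodic=False)[:, 0])
    got = np.array([cf.twist_angle(*q) for q in quads])
    np.testing.assert_allclose(got, expected, atol=1e-4)


def test_twist_angle_collinear_is_undefined():
    with pytest.raises(UndefinedDihedralError):
        cf.twist_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


def test_twist_stats_pooling_arithmetic():
    """Series {-1, 0, +1} degrees pools to average 0, max 1, min -1."""
    model = cf.build_chain(2, "Ibeta")
    base = model.positions
    o2_1 = model.bead_index(0, 1, "O2")
    frames = []
    for target in (-1.0, 0.0, 1.0):
        f = base.copy()
        # rotate residue 1's O2 about the C6-C6 axis to set the dihedral
        c6_0 = base[model.bead_index(0, 0, "C6")]
        c6_1 = base[model.bead_index(0, 1, "C6")]
        from scipy.spatial.transform import Rotation

        axis = (c6_1 - c6_0) / np.linalg.norm(c6_1 - c6_0)
        rot = Rotation.from_rotvec(np.radians(-target) * axis)
        f[o2_1] = rot.apply(f[o2_1] - c6_0) + c6_0
        frames.append(f)
    traj = _traj(frames)
    st = cf.twist_stats(traj, model)
    assert st.n_junctions == 1 and st.n_frames == 3
    assert st.average == pytest.approx(0.0, abs=1e-6)
    assert st.max == pytest.approx(1.0, abs=1e-6)
    assert st.min == pytest.approx(-1.0, abs=1e-6)


def test_twist_stats_needs_two_residues():
    model = cf.build_chain(1, "Ibeta")
    with pytest.raises(InvalidArgumentError):
        cf.twist_stats(_traj(model.positions[None]), model)


# ---------------------------------------------------------------------------
# pair distances
# ---------------------------------------------------------------------------

def test_static_chain_distances_are_exact():
    model = cf.build_chain(6, "Ialpha")
    st = cf.pair_distance_stats(None, model, "O2-O3", "intra")
    assert st.mean == pytest.approx(2.88, abs=1e-9)
    assert st.sd == pytest.approx(0.0, abs=1e-9)
    assert st.n_samples == 6


def test_pair_distance_histogram_normalised(chain20_traj):
    model, _, _, traj = chain20_traj
    st = cf.pair_distance_stats(traj, model, "O2-O6", "intra")
    widths = np.diff(st.bin_edges)
    assert (st.histogram * widths).sum() == pytest.approx(1.0, rel=1e-6)
    assert st.n_samples == traj.n_frames * 20


def test_pair_distance_unknown_spec():
    model = cf.build_chain(3, "Ibeta")
    with pytest.raises(InvalidArgumentError):
        cf.pair_distance_stats(None, model, "O2-O5", "intra")
    with pytest.raises(InvalidArgumentError):
        cf.pair_distance_stats(None, model, "O2-O6", "first")
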