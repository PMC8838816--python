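"""Validation statistics for CG cellulose trajectories.

Four families of observables characterise how well the CG model preserves
the crystalline fibril structure:

* pooled pair-distance distributions over the elastic-network pair classes
  (mean, SD, normalised histogram);
* Kabsch-superposed RMSD of each frame against a fixed reference, averaged
  over the trajectory;
* cross-RMSD: the mean RMSD over all frame pairs drawn from two
  trajectories, a structural distance between simulated systems;
* the fibril twist angle: the signed dihedral over the quadruple
  (O2_i, C6_i, C6_{i+1}, O2_{i+1}) of consecutive residues, pooled over
  junctions, chains and frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .builder import FibrilModel
from .engine import Trajectory
from .errors import InvalidArgumentError, UndefinedDihedralError
from .params import ATOM_TO_SITE, bonded_lookup

__all__ = [
    "DistanceStats",
    "TwistStats",
    "RmsdMatrix",
    "kabsch_rmsd",
    "traj_mean_rmsd",
    "cross_rmsd",
    "twist_angle",
    "twist_stats",
    "pair_distance_stats",
]


@dataclass
class DistanceStats:
    """Pooled statistics of one elastic-network pair class (Å)."""

    pair_label: str
    neighbour_class: str
    mean: float
    sd: float
    histogram: np.ndarray    # densities per bin (integrates to 1)
    bin_edges: np.ndarray
    n_samples: int


@dataclass
class TwistStats:
    """Pooled fibril twist-angle statistics (degrees)."""

    angles: np.ndarray        # pooled series, all junctions/chains/frames
    average: float
    sd: float
    max: float
    min: float
    n_junctions: int
    n_frames: int


@dataclass
class RmsdMatrix:
    """Mean ± SD cross-RMSD per trajectory pair (Å)."""

    entries: dict = field(default_factory=dict)

    def add(self, key_a, key_b, mean, sd, n_pairs):
        self.entries[(key_a, key_b)] = (float(mean), float(sd), int(n_pairs))

    def get(self, key_a, key_b):
        return self.entries[(key_a, key_b)]

    def as_dataframe(self):
        import pandas as pd

        rows = [{"traj_a": a, "traj_b": b, "mean_rmsd": m, "sd": s, "n_pairs": n}
                for (a, b), (m, s, n) in self.entries.items()]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(X: np.ndarray, Y: np.ndarray, superpose: bool = True) -> float:
    """Root-mean-square deviation between two conformations (Å).

    With ``superpose`` the minimum RMSD over rigid rotations and
    translations (optimal Kabsch superposition) is returned; without it,
    the raw positional RMSD.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise InvalidArgumentError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if superpose:
        if len(X) < 3:
            raise InvalidArgumentError("superposition needs at least 3 points")
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # align_vectors warns on exact fits
            rot, _ = Rotation.align_vectors(Xc, Yc)
        Y = rot.apply(Yc)
        X = Xc
    d = X - Y
    return float(np.sqrt((d * d).sum() / len(X)))


def _resolve_reference(traj: Trajectory, reference) -> np.ndarray:
    if isinstance(reference, str):
        if reference == "first":
            return traj.coordinates[0]
        if reference == "last":
            return traj.coordinates[-1]
        raise InvalidArgumentError(f"unknown reference {reference!r}")
    if isinstance(reference, (int, np.integer)):
        return traj.coordinates[int(reference)]
    return np.asarray(reference, dtype=float)


def traj_mean_rmsd(traj: Trajectory, reference="last", superpose: bool = True):
    """Mean and SD of per-frame RMSD against a fixed reference frame.

    ``reference`` may be "first"/"last", a frame index, or an (N, 3) array.
    Returns (mean, sd, per-frame series), all in Å.
    """
    ref = _resolve_reference(traj, reference)
    if ref.shape != traj.coordinates.shape[1:]:
        raise InvalidArgumentError("reference atom count does not match trajectory")
    series = np.array([kabsch_rmsd(ref, frame, superpose=superpose)
                       for frame in traj.coordinates])
    return float(series.mean()), float(series.std()), series


def cross_rmsd(traj_a: Trajectory, traj_b: Trajectory,
               superpose: bool = True, stride: int = 1):
    """RMSD over every (frame_i in A, frame_j in B) pair, optionally strided.

    Returns (mean, sd, n_pairs) in Å — the cross-system structural distance.
    """
    if traj_a.n_beads != traj_b.n_beads:
        raise InvalidArgumentError(
            f"bead sets not mappable: {traj_a.n_beads} vs {traj_b.n_beads}")
    A = traj_a.coordinates[::stride]
    B = traj_b.coordinates[::stride]
    vals = np.empty((len(A), len(B)))
    for i, fa in enumerate(A):
        for j, fb in enumerate(B):
            vals[i, j] = kabsch_rmsd(fa, fb, superpose=superpose)
    return float(vals.mean()), float(vals.std()), vals.size


# ---------------------------------------------------------------------------
# twist dihedral
# ---------------------------------------------------------------------------

def _dihedrals(p1, p2, p3, p4):
    """Signed dihedrals (deg, atan2 convention) for stacked quadruples."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    bad = (np.linalg.norm(n1, axis=-1) < 1e-10) | (np.linalg.norm(n2, axis=-1) < 1e-10)
    return np.degrees(np.arctan2(y, x)), bad


def twist_angle(p_o2_i, p_c6_i, p_c6_j, p_o2_j) -> float:
    """Fibril twist: signed dihedral of (O2_i, C6_i, C6_{i+1}, O2_{i+1}).

    Returns degrees in (-180, 180].  Raises
    :class:`UndefinedDihedralError` when three consecutive points are
    collinear.
    """
    pts = [np.asarray(p, dtype=float) for p in (p_o2_i, p_c6_i, p_c6_j, p_o2_j)]
    ang, bad = _dihedrals(*pts)
    if bad:
        raise UndefinedDihedralError("collinear points: dihedral undefined")
    a = float(ang)
    return 180.0 if a == -180.0 else a


def twist_stats(traj: Trajectory, model: FibrilModel) -> TwistStats:
    """Twist angles for every consecutive-residue junction, chain and frame.

    Statistics (average, SD, max, min) are pooled over the full series.
    Chains with fewer than two residues are skipped with a warning.
    """
    quad_idx = []
    for cid in sorted(np.unique(model.chain_ids)):
        n_res = model.n_residues(cid)
        if n_res < 2:
            warnings.warn(f"chain {cid} has < 2 residues; skipped in twist_stats")
            continue
        for r in range(n_res - 1):
            quad_idx.append((model.bead_index(cid, r, "O2"),
                             model.bead_index(cid, r, "C6"),
                             model.bead_index(cid, r + 1, "C6"),
                             model.bead_index(cid, r + 1, "O2")))
    if not quad_idx:
        raise InvalidArgumentError("no chain with >= 2 residues")
    quad = np.array(quad_idx)
    coords = traj.coordinates
    ang, bad = _dihedrals(coords[:, quad[:, 0]], coords[:, quad[:, 1]],
                          coords[:, quad[:, 2]], coords[:, quad[:, 3]])
    ang = ang[~bad] if bad.any() else ang
    pooled = ang.ravel()
    return TwistStats(
        angles=pooled,
        average=float(pooled.mean()),
        sd=float(pooled.std()),
        max=float(pooled.max()),
        min=float(pooled.min()),
        n_junctions=len(quad),
        n_frames=traj.n_frames,
    )


# ---------------------------------------------------------------------------
# pair distances
# ---------------------------------------------------------------------------

def pair_distance_stats(traj, model: FibrilModel, pair_label: str,
                        neighbour_class: str = "intra",
                        bins="auto") -> DistanceStats:
    """Pooled distance statistics for one elastic-network pair class.

    ``traj`` may be a :class:`Trajectory` or None (static model
    coordinates).  Distances are pooled over all matching pairs in all
    chains and all frames; the histogram is density-normalised
    (Freedman–Diaconis binning by default).
    """
    try:
        bonded_lookup(neighbour_class, pair_label)
    except KeyError:
        raise InvalidArgumentError(
            f"unknown pair spec ({pair_label}, {neighbour_class})") from None
    a, _, b = pair_label.partition("-")
    dr = {"intra": 0, "first": 1, "second": 2}[neighbour_class]

    idx_a, idx_b = [], []
    for cid in sorted(np.unique(model.chain_ids)):
        n_res = model.n_residues(cid)
        for r in range(n_res - dr):
            idx_a.append(model.bead_index(cid, r, a))
            idx_b.append(model.bead_index(cid, r + dr, b))
    idx_a = np.array(idx_a)
    idx_b = np.array(idx_b)

    coords = (traj.coordinates if isinstance(traj, Trajectory)
              else model.positions[None, :, :])
    d = np.linalg.norm(coords[:, idx_a] - coords[:, idx_b], axis=-1).ravel()
    if bins == "auto":
        bins = "fd" if len(d) > 1 and d.std() > 0 else 10
    hist, edges = np.histogram(d, bins=bins, density=len(d) > 0 and d.std() > 0)
    if d.std() == 0:
        # degenerate (static ideal structure): delta distribution
        hist = hist.astype(float)
        widths = np.diff(edges)
        total = (hist * widths).sum()
        if total > 0:
            hist = hist / total
    return DistanceStats(
        pair_label=pair_label,
        neighbour_class=neighbour_class,
        mean=float(d.mean()),
        sd=float(d.std()),
        histogram=hist,
        bin_edges=edges,
        n_samples=len(d),
    )
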