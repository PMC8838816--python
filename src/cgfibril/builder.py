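"""Construction of ideal CG cellulose chains and fibrils, and atomistic mapping.

A cellulose chain is modelled as a sequence of 4-bead D-glucose residues
(beads centred on O2, O3, C6, O6).  The ideal geometry is produced in closed
form from the published elastic-network distances alone:

* the four beads of residue 0 are placed by triangulation so that all six
  intra-residue distances are satisfied exactly;
* residue i is the image of residue 0 under a 2-fold screw along the fibril
  axis (z): a rise of half the second-neighbour distance per residue, with
  every odd residue rotated 180 deg about the axis.  The screw makes every
  second-neighbour distance equal to the repeat exactly, and the radial
  placement of O2, O3 and C6 is chosen so the first-neighbour distances hold.

O2 and C6 are kept in the y=0 plane on the same side of the screw axis, so
the ideal chain is an untwisted flat ribbon: the twist dihedral
(O2_i, C6_i, C6_{i+1}, O2_{i+1}) is exactly zero at every junction.

Fibrils replicate the chain on a 2-D lattice with allomorph-specific
spacings, axial staggers and (for type-II) antiparallel packing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .errors import InvalidArgumentError, InvalidModelError, MappingError
from .params import (
    ALLOMORPHS,
    ATOM_TO_SITE,
    BEAD_CHARGES,
    BEAD_MASSES,
    INTER_ATOMS,
    INTRA_PAIRS,
    SITE_LABELS,
    SITE_TO_ATOM,
    SITE_TO_BEAD_TYPE,
    bonded_lookup,
)

__all__ = [
    "BeadSite",
    "FibrilModel",
    "LatticeSpec",
    "LATTICE_PRESETS",
    "build_chain",
    "build_fibril",
    "map_atomistic",
    "sch_connectivity",
    "residue_template",
]

#: rise per residue along the fibril axis (Å): half the 2nd-neighbour repeat
_RISE = bonded_lookup("second", "O2-O2")[0] / 2.0

_BOX_MARGIN = 20.0  # Å of padding around the structure in the stored box


@dataclass(frozen=True)
class BeadSite:
    """One CG bead: identity, provenance atom, position and physical attributes."""

    bead_index: int
    chain_id: int
    residue_index: int
    site_label: str
    position: np.ndarray  # (3,) Å
    mass: float | None = None
    charge: float = 0.0

    @property
    def source_atom(self) -> str:
        return SITE_TO_ATOM[self.site_label]


@dataclass
class LatticeSpec:
    """2-D interchain packing: spacings in Å, shear angle in degrees.

    ``a`` is the in-sheet chain-to-chain spacing (x), ``b`` the sheet
    stacking distance (y), ``gamma`` the angle between the two lattice
    vectors.  ``z_stagger_col``/``z_stagger_row`` are axial offsets applied
    per column/row (the c/4 stagger of native cellulose packing), and
    ``antiparallel`` flips every other chain (checkerboard), the defining
    feature of type-II packing.
    """

    a: float = 8.2
    b: float = 3.9
    gamma: float = 90.0
    z_stagger_col: float = 0.0
    z_stagger_row: float = 2.61
    antiparallel: bool = False


#: per-allomorph packing defaults.  The allomorphs share one bonded model;
#: they differ in how chains pack: Ialpha carries the triclinic shear (axial
#: stagger in both lattice directions), Ibeta the monoclinic stagger along
#: one direction only, and type-II antiparallel chains with wider, oppositely
#: sheared stacking.  Spacings are widened relative to the crystallographic
#: cells so that CG beads of adjacent chains keep >= 2 Å clearance.
LATTICE_PRESETS: dict[str, LatticeSpec] = {
    "Ialpha": LatticeSpec(a=8.2, b=3.9, z_stagger_col=2.61, z_stagger_row=2.61),
    "Ibeta": LatticeSpec(a=8.2, b=3.9, z_stagger_col=0.0, z_stagger_row=2.61),
    "II": LatticeSpec(a=8.6, b=6.0, z_stagger_col=0.0, z_stagger_row=-2.61,
                      antiparallel=True),
}


@dataclass
class FibrilModel:
    """Ordered chains of 4-bead residues plus box and allomorph tag.

    Beads are stored chain-major, residue-major, in fixed site order
    CG1, CG2, CG3, CG4; ``positions`` are in Å.  ``bead_types``/``masses``/
    ``charges`` are filled by :func:`cgfibril.topology.assign_bead_types`.
    """

    allomorph: str
    positions: np.ndarray           # (N, 3) Å
    chain_ids: np.ndarray           # (N,) int
    residue_indices: np.ndarray     # (N,) int, 0-based within each chain
    site_labels: np.ndarray         # (N,) unicode, CG1..CG4
    box_vectors: np.ndarray         # (3, 3) Å
    provenance: str = "built"
    bead_types: np.ndarray | None = None
    masses: np.ndarray | None = None
    charges: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.chain_ids = np.asarray(self.chain_ids, dtype=int)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.site_labels = np.asarray(self.site_labels)
        self.box_vectors = np.asarray(self.box_vectors, dtype=float).reshape(3, 3)
        n = len(self.positions)
        if not (len(self.chain_ids) == len(self.residue_indices)
                == len(self.site_labels) == n):
            raise InvalidModelError("bead attribute arrays have inconsistent lengths")
        unknown = set(np.unique(self.site_labels)) - set(SITE_LABELS)
        if unknown:
            raise InvalidModelError(f"unknown site label(s): {sorted(unknown)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_ids))

    def chain_indices(self, chain_id: int) -> np.ndarray:
        """Global bead indices of one chain, in storage order."""
        return np.nonzero(self.chain_ids == chain_id)[0]

    def n_residues(self, chain_id: int = 0) -> int:
        return int(self.residue_indices[self.chain_ids == chain_id].max()) + 1

    @property
    def source_atoms(self) -> np.ndarray:
        """Per-bead source atom names (O2/O3/C6/O6)."""
        return np.array([SITE_TO_ATOM[s] for s in self.site_labels])

    def bead(self, index: int) -> BeadSite:
        return BeadSite(
            bead_index=index,
            chain_id=int(self.chain_ids[index]),
            residue_index=int(self.residue_indices[index]),
            site_label=str(self.site_labels[index]),
            position=self.positions[index].copy(),
            mass=None if self.masses is None else float(self.masses[index]),
            charge=0.0 if self.charges is None else float(self.charges[index]),
        )

    def bead_index(self, chain_id: int, residue_index: int, atom: str) -> int:
        """Global index of the bead for ``atom`` (O2/O3/C6/O6 or CG label)."""
        site = ATOM_TO_SITE.get(atom, atom)
        mask = ((self.chain_ids == chain_id)
                & (self.residue_indices == residue_index)
                & (self.site_labels == site))
        idx = np.nonzero(mask)[0]
        if len(idx) != 1:
            raise InvalidArgumentError(
                f"no unique bead for chain {chain_id} residue {residue_index} {atom}")
        return int(idx[0])

    def with_positions(self, positions: np.ndarray) -> "FibrilModel":
        """Copy of the model with replaced coordinates (Å)."""
        new = replace(self, positions=np.array(positions, dtype=float))
        return new

    def copy(self) -> "FibrilModel":
        new = replace(self)
        new.positions = self.positions.copy()
        if self.bead_types is not None:
            new.bead_types = self.bead_types.copy()
        if self.masses is not None:
            new.masses = self.masses.copy()
        if self.charges is not None:
            new.charges = self.charges.copy()
        return new


# ---------------------------------------------------------------------------
# closed-form residue geometry
# ---------------------------------------------------------------------------

def _intra(a: str, b: str) -> float:
    return bonded_lookup("intra", f"{a}-{b}")[0]


def _trilaterate(p1, p2, p3, d1, d2, d3, branch=1.0):
    """Point at distances d1/d2/d3 from p1/p2/p3; ``branch`` picks the mirror."""
    ex = (p2 - p1) / np.linalg.norm(p2 - p1)
    i = ex @ (p3 - p1)
    ey = p3 - p1 - i * ex
    ey = ey / np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    d = np.linalg.norm(p2 - p1)
    j = ey @ (p3 - p1)
    x = (d1 * d1 - d2 * d2 + d * d) / (2 * d)
    y = (d1 * d1 - d3 * d3 + i * i + j * j - 2 * i * x) / (2 * j)
    z2 = d1 * d1 - x * x - y * y
    z = math.sqrt(max(z2, 0.0))
    return p1 + x * ex + y * ey + branch * z * ez


@lru_cache(maxsize=1)
def residue_template() -> dict:
    """Positions (Å) of the four sites of residue 0, keyed by source atom.

    Derived entirely from the published distances: cylinder radii of O2, O3
    and C6 about the screw axis follow from the first-neighbour distances
    and the axial rise; O2 and C6 sit in the y=0 plane (untwisted ribbon),
    O3 follows by triangulation against both, and O6 by trilateration from
    the other three (it carries no inter-residue bonds).
    """
    h = _RISE
    radius = {a: math.sqrt(bonded_lookup("first", f"{a}-{a}")[0] ** 2 - h * h) / 2.0
              for a in INTER_ATOMS}
    o2 = np.array([radius["O2"], 0.0, 0.0])
    # same-side placement: the junction dihedral comes out cis (0 deg)
    z6 = math.sqrt(_intra("O2", "C6") ** 2 - (radius["O2"] - radius["C6"]) ** 2)
    c6 = np.array([radius["C6"], 0.0, z6])

    # O3: on its cylinder, at the right distances from O2 and C6.
    r3, dA, dB = radius["O3"], _intra("O2", "O3"), _intra("O3", "C6")
    # eliminate y via the cylinder equation; z is affine in x, then solve the
    # resulting quadratic in x (the root inside the cylinder radius)
    cz, cx, ox = c6[2], c6[0], o2[0]
    # z = (dA^2 - dB^2 - ox^2 + cx^2 + cz^2 - 2(cx-ox) x) / (2 cz)
    p = (dA * dA - dB * dB - ox * ox + cx * cx + cz * cz) / (2 * cz)
    q = -(cx - ox) / cz
    # z^2 = dA^2 - r3^2 + 2 ox x - ox^2
    a2 = q * q
    a1 = 2 * p * q - 2 * ox
    a0 = p * p - dA * dA + r3 * r3 + ox * ox
    disc = a1 * a1 - 4 * a2 * a0
    if a2 < 1e-12:
        x3 = -a0 / a1
    else:
        x3 = (-a1 - math.sqrt(disc)) / (2 * a2)
        if abs(x3) > r3:
            x3 = (-a1 + math.sqrt(disc)) / (2 * a2)
    z3 = p + q * x3
    y3 = math.sqrt(r3 * r3 - x3 * x3)
    o3 = np.array([x3, y3, z3])

    o6 = _trilaterate(o2, o3, c6,
                      _intra("O2", "O6"), _intra("O3", "O6"), _intra("C6", "O6"),
                      branch=1.0)
    return {"O2": o2, "O3": o3, "C6": c6, "O6": o6}


def _chain_coordinates(n_residues: int) -> np.ndarray:
    """(4*n, 3) ideal chain coordinates in Å, site order CG1..CG4 per residue."""
    tmpl = residue_template()
    base = np.array([tmpl[SITE_TO_ATOM[s]] for s in SITE_LABELS])
    coords = np.empty((n_residues, 4, 3))
    for i in range(n_residues):
        r = base.copy()
        if i % 2 == 1:  # 2-fold screw: 180 deg about the z axis
            r[:, 0] *= -1.0
            r[:, 1] *= -1.0
        r[:, 2] += _RISE * i
        coords[i] = r
    return coords.reshape(-1, 3)


def _bounding_box(positions: np.ndarray) -> np.ndarray:
    extent = positions.max(axis=0) - positions.min(axis=0) + 2 * _BOX_MARGIN
    return np.diag(extent)


def _check_allomorph(allomorph: str) -> str:
    if allomorph not in ALLOMORPHS:
        raise InvalidArgumentError(
            f"unknown allomorph {allomorph!r}; expected one of {ALLOMORPHS}")
    return allomorph


def build_chain(n_residues: int, allomorph: str = "Ibeta") -> FibrilModel:
    """Ideal single chain: every elastic-network distance at its r0.

    Intra-residue distances are exact by triangulation; first/second
    neighbour O2-O2, O3-O3, C6-C6 distances are exact by the screw
    construction.  The chain axis is z, residues are 0-indexed.
    """
    _check_allomorph(allomorph)
    if n_residues < 1:
        raise InvalidArgumentError("n_residues must be >= 1")
    pos = _chain_coordinates(n_residues)
    n = 4 * n_residues
    return FibrilModel(
        allomorph=allomorph,
        positions=pos,
        chain_ids=np.zeros(n, dtype=int),
        residue_indices=np.repeat(np.arange(n_residues), 4),
        site_labels=np.tile(np.array(SITE_LABELS), n_residues),
        box_vectors=_bounding_box(pos),
        provenance="built",
    )


def build_fibril(
    n_chains: int,
    layout: tuple[int, int],
    n_residues: int,
    allomorph: str = "Ibeta",
    lattice: LatticeSpec | None = None,
    min_clearance: float = 2.0,
) -> FibrilModel:
    """Chains replicated on a 2-D lattice with allomorph-specific packing.

    ``layout`` is (n_cols, n_rows) with n_cols*n_rows == n_chains.  Raises
    if any two beads from different chains come closer than
    ``min_clearance`` Å (an overlapping lattice spec).
    """
    _check_allomorph(allomorph)
    if n_chains < 1:
        raise InvalidArgumentError("n_chains must be >= 1")
    ncol, nrow = layout
    if ncol * nrow != n_chains:
        raise InvalidArgumentError(
            f"layout {ncol}x{nrow} inconsistent with n_chains={n_chains}")
    lat = lattice if lattice is not None else LATTICE_PRESETS[allomorph]

    chain_pos = _chain_coordinates(n_residues)
    repeat = 2 * _RISE
    gamma = math.radians(lat.gamma)
    va = np.array([lat.a, 0.0])
    vb = np.array([lat.b * math.cos(gamma), lat.b * math.sin(gamma)])

    all_pos, chain_ids, res_idx, labels = [], [], [], []
    cid = 0
    for j in range(nrow):
        for i in range(ncol):
            p = chain_pos.copy()
            if lat.antiparallel and (i + j) % 2 == 1:
                # proper 180 deg rotation about x: chain runs the other way
                p[:, 1] *= -1.0
                p[:, 2] *= -1.0
                p[:, 2] -= p[:, 2].min() - chain_pos[:, 2].min()
                # keep the screw parities of neighbouring chains interleaved
                # (the reversed chain's residue parity pattern depends on
                # whether the chain length is even or odd)
                p[:, 2] += _RISE * (n_residues % 2)
            zoff = (i * lat.z_stagger_col + j * lat.z_stagger_row) % repeat
            xy = i * va + j * vb
            p += np.array([xy[0], xy[1], zoff])
            all_pos.append(p)
            chain_ids.append(np.full(len(p), cid))
            res_idx.append(np.repeat(np.arange(n_residues), 4))
            labels.append(np.tile(np.array(SITE_LABELS), n_residues))
            cid += 1
    positions = np.concatenate(all_pos)
    model = FibrilModel(
        allomorph=allomorph,
        positions=positions,
        chain_ids=np.concatenate(chain_ids),
        residue_indices=np.concatenate(res_idx),
        site_labels=np.concatenate(labels),
        box_vectors=_bounding_box(positions),
        provenance="built",
        metadata={"layout": (ncol, nrow), "lattice": lat},
    )
    if n_chains > 1:
        d = _min_interchain_distance(model)
        if d < min_clearance:
            raise InvalidArgumentError(
                f"overlapping lattice spec: interchain bead distance "
                f"{d:.2f} Å < {min_clearance} Å")
    return model


def _min_interchain_distance(model: FibrilModel) -> float:
    from scipy.spatial import cKDTree

    best = math.inf
    trees = {c: cKDTree(model.positions[model.chain_ids == c])
             for c in np.unique(model.chain_ids)}
    cids = sorted(trees)
    for a_i, ca in enumerate(cids):
        pa = model.positions[model.chain_ids == ca]
        for cb in cids[a_i + 1:]:
            d = trees[cb].query(pa, k=1)[0].min()
            best = min(best, d)
    return best


# ---------------------------------------------------------------------------
# SCH connectivity (the plane triangulation of a chain)
# ---------------------------------------------------------------------------

def sch_connectivity(model: FibrilModel, chain_id: int | None = None):
    """Elastic-network pair list of the chain triangulation.

    Returns tuples ``(i, j, neighbour_class, pair_label)`` with global bead
    indices.  Per residue the six intra pairs; per adjacent and per
    second-neighbour residue pair the three O2-O2 / O3-O3 / C6-C6 pairs.
    O6 carries no inter-residue pairs, and chains are never cross-linked.
    For an n-residue chain the count is 6n + 3(n-1) + 3(n-2) = 12n - 9
    (n >= 2; 6 pairs for n = 1).
    """
    chains = [chain_id] if chain_id is not None else sorted(np.unique(model.chain_ids))
    pairs = []
    for cid in chains:
        mask = model.chain_ids == cid
        if not mask.any():
            raise InvalidArgumentError(f"no such chain: {cid}")
        n_res = int(model.residue_indices[mask].max()) + 1
        # index lookup table (residue, site) -> global bead index
        table = {}
        for g in np.nonzero(mask)[0]:
            table[(int(model.residue_indices[g]), str(model.site_labels[g]))] = int(g)
        for r in range(n_res):
            for lbl in INTRA_PAIRS:
                a, _, b = lbl.partition("-")
                pairs.append((table[(r, ATOM_TO_SITE[a])],
                              table[(r, ATOM_TO_SITE[b])], "intra", lbl))
            for cls, dr in (("first", 1), ("second", 2)):
                if r + dr >= n_res:
                    continue
                for atom in INTER_ATOMS:
                    pairs.append((table[(r, ATOM_TO_SITE[atom])],
                                  table[(r + dr, ATOM_TO_SITE[atom])],
                                  cls, f"{atom}-{atom}"))
    return pairs


# ---------------------------------------------------------------------------
# atomistic mapping
# ---------------------------------------------------------------------------

def map_atomistic(structure, allomorph: str = "Ibeta") -> FibrilModel:
    """Map an atomistic structure onto the 4-bead representation.

    ``structure`` is an MDAnalysis Universe/AtomGroup or a PDB/GRO path.
    One bead is produced per (residue, site), its position copied exactly
    from the named atom (O2, O3, C6, O6).  Residue and chain ordering is
    preserved.  A residue missing any of the four atoms raises
    :class:`MappingError` naming the chain and residue.
    """
    import MDAnalysis as mda

    if isinstance(structure, (str,)) or hasattr(structure, "__fspath__"):
        structure = mda.Universe(str(structure))
    atoms = structure.atoms if hasattr(structure, "atoms") else structure
    if len(atoms) == 0:
        raise InvalidArgumentError("empty selection: no atoms to map")

    positions, chain_ids, res_idx, labels = [], [], [], []
    cid_of: dict = {}
    next_local: dict = {}
    for res in atoms.residues:
        segid = res.segment.segid
        cid = cid_of.setdefault(segid, len(cid_of))
        local_r = next_local.get(cid, 0)
        next_local[cid] = local_r + 1
        # restrict to the selection: a residue whose site atom was excluded
        # is treated as missing that atom
        group = atoms.intersection(res.atoms)
        names = {a.name: a for a in group}
        for site in SITE_LABELS:
            atom_name = SITE_TO_ATOM[site]
            if atom_name not in names:
                raise MappingError(
                    f"chain {segid!r} residue {res.resid} "
                    f"({res.resname}) lacks atom {atom_name}")
            positions.append(names[atom_name].position.copy())
            chain_ids.append(cid)
            res_idx.append(local_r)
            labels.append(site)
    positions = np.array(positions, dtype=float)
    try:
        dims = atoms.universe.dimensions
    except Exception:
        dims = None
    if dims is not None and dims[:3].any():
        box = np.diag(dims[:3]).astype(float)
    else:
        box = _bounding_box(positions)
    return FibrilModel(
        allomorph=allomorph,
        positions=positions,
        chain_ids=np.array(chain_ids),
        residue_indices=np.array(res_idx),
        site_labels=np.array(labels),
        box_vectors=box,
        provenance="mapped",
    )
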