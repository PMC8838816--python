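"""Structure, trajectory and configuration I/O, plus fixture generation.

Coordinates are Å everywhere in memory; GRO files are nm on disk (the
underlying readers/writers convert).  PDB files carry one chain letter per
cellulose chain, 1-based residue numbers, residue name BGC, and the CG
beads keep their source-atom names (O2/O3/C6/O6) so that built and mapped
models are interchangeable downstream.

Structure files go through MDAnalysis; multi-frame trajectories (GRO,
optionally XTC) go through mdtraj.
"""

from __future__ import annotations

import dataclasses
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .builder import (
    FibrilModel,
    LatticeSpec,
    build_chain,
    build_fibril,
)
from .engine import EngineConfig, Trajectory
from .errors import FormatError, InvalidArgumentError, ParseError
from .params import ATOM_TO_SITE, SITE_TO_ATOM

__all__ = [
    "PackageConfig",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "make_fixture",
]

_CHAIN_LETTERS = string.ascii_uppercase + string.ascii_lowercase + string.digits
_CG_ATOM_NAMES = frozenset(ATOM_TO_SITE)


def _chain_letter(cid: int) -> str:
    return _CHAIN_LETTERS[cid % len(_CHAIN_LETTERS)]


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _model_to_universe(model: FibrilModel):
    import MDAnalysis as mda

    n = model.n_beads
    # global residue index per bead
    res_key = {}
    atom_resindex = np.empty(n, dtype=int)
    res_seg, resids = [], []
    seg_key = {}
    for i in range(n):
        cid = int(model.chain_ids[i])
        key = (cid, int(model.residue_indices[i]))
        if key not in res_key:
            res_key[key] = len(res_key)
            resids.append(int(model.residue_indices[i]) + 1)
            res_seg.append(seg_key.setdefault(cid, len(seg_key)))
        atom_resindex[i] = res_key[key]
    u = mda.Universe.empty(
        n_atoms=n, n_residues=len(res_key), n_segments=len(seg_key),
        atom_resindex=atom_resindex, residue_segindex=np.array(res_seg),
        trajectory=True)
    u.add_TopologyAttr("names", [SITE_TO_ATOM[s] for s in model.site_labels])
    u.add_TopologyAttr("resnames", ["BGC"] * len(res_key))
    u.add_TopologyAttr("resids", np.array(resids))
    segids = [_chain_letter(c) for c in sorted(seg_key, key=seg_key.get)]
    u.add_TopologyAttr("segids", segids)
    u.add_TopologyAttr("chainIDs",
                       [_chain_letter(int(c)) for c in model.chain_ids])
    u.add_TopologyAttr("elements",
                       ["C" if SITE_TO_ATOM[s] == "C6" else "O"
                        for s in model.site_labels])
    u.atoms.positions = model.positions.astype(np.float32)
    d = np.diag(model.box_vectors)
    u.dimensions = [d[0], d[1], d[2], 90.0, 90.0, 90.0]
    return u


def write_structure(model: FibrilModel, path: str) -> str:
    """Write a model to PDB or GRO (by extension)."""
    u = _model_to_universe(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return str(path)


def read_structure(path: str):
    """Read a PDB/GRO file.

    If every residue consists of exactly the four CG site atoms (O2, O3,
    C6, O6) the file is interpreted as a CG model and an untyped
    :class:`FibrilModel` is returned; otherwise the MDAnalysis Universe is
    returned for downstream atomistic mapping.  Chain boundaries come from
    chain/segment identifiers when present, else from residue-number
    resets (the GRO convention used by :func:`write_structure`).
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        _ = u.atoms.positions
    except Exception as exc:
        raise ParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise ParseError(f"no atoms in {path}")

    is_cg = all(
        len(res.atoms) == 4 and {a.name for a in res.atoms} == _CG_ATOM_NAMES
        for res in u.residues)
    if not is_cg:
        return u

    # chain assignment: explicit identifiers, else resid resets
    try:
        per_res_chain = [str(r.segid) or "?" for r in u.residues]
        use_segids = len(set(per_res_chain)) > 1
    except Exception:
        use_segids = False
    positions, chain_ids, res_idx, labels = [], [], [], []
    cid, prev_resid, prev_seg = 0, None, None
    local_r = -1
    for res in u.residues:
        seg = str(getattr(res, "segid", "")) if use_segids else None
        if prev_resid is not None and (
                (use_segids and seg != prev_seg)
                or (not use_segids and res.resid <= prev_resid)):
            cid += 1
            local_r = -1
        local_r += 1
        prev_resid, prev_seg = res.resid, seg
        names = {a.name: a for a in res.atoms}
        for atom_name in ("O2", "O3", "C6", "O6"):
            positions.append(names[atom_name].position.copy())
            chain_ids.append(cid)
            res_idx.append(local_r)
            labels.append(ATOM_TO_SITE[atom_name])
    dims = u.dimensions
    if dims is not None and dims[:3].any():
        box = np.diag(dims[:3]).astype(float)
    else:
        pos = np.array(positions)
        box = np.diag(pos.max(axis=0) - pos.min(axis=0) + 40.0)
    return FibrilModel(
        allomorph="Ibeta",
        positions=np.array(positions, dtype=float),
        chain_ids=np.array(chain_ids),
        residue_indices=np.array(res_idx),
        site_labels=np.array(labels),
        box_vectors=box,
        provenance="mapped",
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _mdtraj_topology(model: FibrilModel):
    import mdtraj as md
    from mdtraj.core import element as elem

    top = md.Topology()
    for cid in sorted(np.unique(model.chain_ids)):
        chain = top.add_chain()
        mask = model.chain_ids == cid
        n_res = int(model.residue_indices[mask].max()) + 1
        for r in range(n_res):
            res = top.add_residue("BGC", chain, resSeq=r + 1)
            for g in np.nonzero(mask & (model.residue_indices == r))[0]:
                name = SITE_TO_ATOM[str(model.site_labels[g])]
                e = elem.carbon if name == "C6" else elem.oxygen
                top.add_atom(name, e, res)
    return top


def write_trajectory(traj: Trajectory, path: str,
                     model: FibrilModel | None = None) -> str:
    """Write a multi-frame GRO (or XTC) trajectory.

    Frame order and times are preserved; GRO stores positions at 0.001 nm
    precision (0.01 Å), which bounds the round-trip error.  XTC output
    needs no model; GRO benefits from one for residue/chain metadata.
    """
    import mdtraj as md

    if traj.n_frames < 1:
        raise FormatError("empty trajectory")
    if model is not None:
        top = _mdtraj_topology(model)
    else:
        top = _anonymous_topology(traj.n_beads)
    box = np.diag(traj.box_vectors) / 10.0
    t = md.Trajectory(
        xyz=(traj.coordinates / 10.0).astype(np.float32),
        topology=top,
        time=traj.times,
        unitcell_lengths=np.tile(box, (traj.n_frames, 1)),
        unitcell_angles=np.full((traj.n_frames, 3), 90.0),
    )
    t.save(str(path))
    return str(path)


def _anonymous_topology(n_beads: int):
    import mdtraj as md
    from mdtraj.core import element as elem

    top = md.Topology()
    chain = top.add_chain()
    res = top.add_residue("CG", chain)
    for i in range(n_beads):
        top.add_atom(f"B{i + 1}", elem.oxygen, res)
    return top


def read_trajectory(path: str, model: FibrilModel | None = None) -> Trajectory:
    """Read a multi-frame GRO (or XTC, with ``model`` for topology)."""
    import mdtraj as md

    try:
        if str(path).endswith(".xtc"):
            if model is None:
                raise InvalidArgumentError("XTC input needs a model for topology")
            t = md.load(str(path), top=_mdtraj_topology(model))
        else:
            t = md.load(str(path))
    except (InvalidArgumentError,):
        raise
    except Exception as exc:
        raise FormatError(f"cannot read trajectory {path}: {exc}") from exc
    if t.n_frames == 0:
        raise FormatError(f"no frames in {path}")
    if t.unitcell_lengths is not None:
        box = np.diag(t.unitcell_lengths[0] * 10.0)
    else:
        box = np.eye(3)
    times = (t.time if t.time is not None
             else np.arange(t.n_frames, dtype=float))
    return Trajectory(
        times=np.asarray(times, dtype=float),
        coordinates=np.asarray(t.xyz, dtype=float) * 10.0,
        box_vectors=box,
        metadata={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0, n_residues: int = 5,
                 sigma: float = 0.1, allomorph: str = "Ibeta",
                 outdir: str | None = None) -> dict:
    """Deterministic small test structures.

    Kinds: ``ideal_chain`` (builder output), ``perturbed_chain`` (ideal +
    Gaussian displacement of width ``sigma`` Å), ``mini_fibril`` (2x2
    chains), ``rotated_copy`` (ideal chain plus a rigidly transformed copy
    with the transform recorded).  Byte-identical given the same seed.
    If ``outdir`` is given, GRO files are written there.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    out: dict = {"kind": kind, "seed": seed}
    if kind == "ideal_chain":
        out["model"] = build_chain(n_residues, allomorph)
    elif kind == "perturbed_chain":
        model = build_chain(n_residues, allomorph)
        noisy = model.positions + rng.normal(0.0, sigma, model.positions.shape)
        out["model"] = model.with_positions(noisy)
        out["sigma"] = sigma
    elif kind == "mini_fibril":
        out["model"] = build_fibril(4, (2, 2), n_residues, allomorph)
    elif kind == "rotated_copy":
        model = build_chain(n_residues, allomorph)
        rot = Rotation.random(random_state=np.random.RandomState(seed))
        translation = rng.uniform(-10.0, 10.0, 3)
        moved = model.with_positions(rot.apply(model.positions) + translation)
        out.update(model=model, rotated=moved,
                   rotation=rot.as_matrix(), translation=translation)
    else:
        raise InvalidArgumentError(f"unknown fixture kind {kind!r}")

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        files = []
        for name in ("model", "rotated"):
            if name in out:
                p = os.path.join(outdir, f"{kind}_{name}.gro")
                write_structure(out[name], p)
                files.append(p)
        out["files"] = files
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PackageConfig:
    """Package-level configuration; YAML round-trips losslessly.

    Units policy is fixed: Å in memory and user-facing output, nm inside
    topology and GRO files.
    """

    engine: EngineConfig = field(default_factory=EngineConfig)
    lattice_overrides: dict = field(default_factory=dict)  # allomorph -> LatticeSpec
    seed: int = 2022
    verbosity: str = "info"

    def to_dict(self) -> dict:
        eng = dataclasses.asdict(self.engine)
        if eng["box"] is not None:
            eng["box"] = np.asarray(eng["box"]).tolist()
        return {
            "engine": eng,
            "lattice_overrides": {k: dataclasses.asdict(v)
                                  for k, v in self.lattice_overrides.items()},
            "seed": self.seed,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PackageConfig":
        eng = dict(data.get("engine", {}))
        if eng.get("box") is not None:
            eng["box"] = np.asarray(eng["box"], dtype=float)
        return cls(
            engine=EngineConfig(**eng),
            lattice_overrides={k: LatticeSpec(**v)
                               for k, v in data.get("lattice_overrides", {}).items()},
            seed=int(data.get("seed", 2022)),
            verbosity=str(data.get("verbosity", "info")),
        )

    def save(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return str(path)

    @classmethod
    def load(cls, path: str) -> "PackageConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def __eq__(self, other):
        if not isinstance(other, PackageConfig):
            return NotImplemented
        a, b = self.to_dict(), other.to_dict()
        return a == b
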