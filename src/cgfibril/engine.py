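"""Minimal CG molecular dynamics for the 4-bead cellulose model.

Provides energies and exact analytic forces for the harmonic elastic
network plus truncated-and-shifted Lennard-Jones (12-6) nonbonded terms,
steepest-descent energy minimization, and NVT dynamics with a BAOAB
Langevin integrator (default) or the stochastic velocity-rescaling
thermostat; with the thermostat off the integrator is plain velocity
Verlet (NVE).  Electrostatics degenerate to a no-op because every
cellulose bead is uncharged.

Internal units are GROMACS-style (nm, ps, amu, kJ/mol); the public API
speaks Å for coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .builder import FibrilModel
from .errors import (
    InvalidArgumentError,
    InvalidModelError,
    MissingParameterError,
    NumericalFailure,
)
from .params import A_PER_NM, KB, NM_PER_A
from .topology import BondTerm, NonbondedTable

__all__ = [
    "EngineConfig",
    "Trajectory",
    "System",
    "bond_energy",
    "lj_energy",
    "total_energy_forces",
    "minimize",
    "run_dynamics",
]


@dataclass
class EngineConfig:
    """Simulation settings.

    The defaults mirror the production protocol of the parameterization:
    0.02 ps timestep, 300 K, 1.1 nm Lennard-Jones cutoff.  ``friction`` is
    the Langevin collision rate (ps^-1); ``tau_t`` the velocity-rescale
    coupling time (ps).  Vacuum (pbc off) is the default; with pbc on, an
    orthorhombic ``box`` in nm is required.
    """

    timestep: float = 0.02          # ps
    temperature: float = 300.0      # K
    thermostat: str = "langevin"    # langevin | v_rescale | none
    friction: float = 1.0           # ps^-1 (langevin)
    tau_t: float = 1.0              # ps (v_rescale)
    lj_cutoff: float = 1.1          # nm
    seed: int = 2022
    pbc: bool = False
    box: np.ndarray | None = None   # (3,3) nm, orthorhombic
    neighbor_skin: float = 0.3      # nm

    def __post_init__(self):
        if self.timestep <= 0:
            raise InvalidArgumentError("timestep must be > 0")
        if self.temperature < 0:
            raise InvalidArgumentError("temperature must be >= 0")
        if self.lj_cutoff <= 0:
            raise InvalidArgumentError("lj_cutoff must be > 0")
        if self.thermostat not in ("langevin", "v_rescale", "none"):
            raise InvalidArgumentError(f"unknown thermostat {self.thermostat!r}")


@dataclass
class Trajectory:
    """Time-ordered frames of bead positions (Å)."""

    times: np.ndarray               # (F,) ps
    coordinates: np.ndarray         # (F, N, 3) Å
    box_vectors: np.ndarray         # (3, 3) Å
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or len(self.coordinates) != len(self.times):
            raise InvalidArgumentError("frames and times are inconsistent")
        if len(self.times) < 1:
            raise InvalidArgumentError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, index: int) -> np.ndarray:
        return self.coordinates[index]

    def sliced(self, start=None, stop=None, step=None) -> "Trajectory":
        sl = slice(start, stop, step)
        return Trajectory(self.times[sl], self.coordinates[sl],
                          self.box_vectors, dict(self.metadata))


# ---------------------------------------------------------------------------
# elementary potentials (scalar helpers; Å in, kJ/mol out)
# ---------------------------------------------------------------------------

def bond_energy(r: float, r0: float, k: float) -> tuple[float, float]:
    """Harmonic bond energy and radial force at distance r.

    r, r0 in Å; k in kJ mol^-1 nm^-2.  Returns (V [kJ/mol],
    dV/dr [kJ mol^-1 nm^-1]); the force on the bond is -dV/dr.
    """
    if r <= 0:
        raise InvalidArgumentError("r must be > 0")
    dr = (r - r0) * NM_PER_A
    return 0.5 * k * dr * dr, k * dr


def lj_energy(r: float, sigma: float, epsilon: float,
              cutoff: float | None = 1.1, shift: bool = True) -> float:
    """Truncated Lennard-Jones 12-6 energy (potential-shifted by default).

    r and sigma in Å, epsilon in kJ/mol, cutoff in nm.  Returns exactly 0
    beyond the cutoff; ``cutoff=None`` disables truncation.
    """
    if r <= 0:
        raise InvalidArgumentError("r must be > 0")
    if cutoff is not None and r * NM_PER_A > cutoff:
        return 0.0
    sr6 = (sigma / r) ** 6
    v = 4.0 * epsilon * (sr6 * sr6 - sr6)
    if shift and cutoff is not None:
        src6 = (sigma * NM_PER_A / cutoff) ** 6
        v -= 4.0 * epsilon * (src6 * src6 - src6)
    return v


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------

class System:
    """Typed model + bonds + nonbonded table compiled to force-field arrays."""

    def __init__(self, model: FibrilModel, bonds: list[BondTerm],
                 nonbonded: NonbondedTable, config: EngineConfig):
        if model.bead_types is None or model.masses is None:
            raise InvalidModelError("model is untyped; run assign_bead_types first")
        self.config = config
        self.n = model.n_beads
        self.pos = model.positions * NM_PER_A          # nm
        self.masses = model.masses.astype(float)
        self.bead_types = model.bead_types

        if not np.isfinite(self.pos).all():
            raise InvalidModelError("non-finite coordinates")
        # coincident beads make LJ forces blow up immediately — refuse early
        if self.n > 1:
            d, _ = cKDTree(self.pos).query(self.pos, k=2)
            if d[:, 1].min() < 1e-6:
                raise InvalidModelError("two beads at (numerically) identical positions")

        self.bi = np.array([b.i for b in bonds], dtype=np.int64)
        self.bj = np.array([b.j for b in bonds], dtype=np.int64)
        self.b0 = np.array([b.r0 for b in bonds]) * NM_PER_A
        self.bk = np.array([b.k for b in bonds], dtype=float)

        # per-(type,type) LJ tables; every pair of types present must resolve
        types = sorted(set(self.bead_types))
        self.type_code = np.array([types.index(t) for t in self.bead_types],
                                  dtype=np.int64)
        t = len(types)
        self._sig = np.zeros((t, t))
        self._eps = np.zeros((t, t))
        rc = config.lj_cutoff
        self._vshift = np.zeros((t, t))
        for a in range(t):
            for b in range(a, t):
                sigma, eps = nonbonded.lookup(types[a], types[b])  # may raise
                s_nm = sigma * NM_PER_A
                sr6 = (s_nm / rc) ** 6
                self._sig[a, b] = self._sig[b, a] = s_nm
                self._eps[a, b] = self._eps[b, a] = eps
                self._vshift[a, b] = self._vshift[b, a] = 4.0 * eps * (sr6 * sr6 - sr6)

        # exclusions: every bonded pair, as sorted integer keys
        key = np.minimum(self.bi, self.bj) * self.n + np.maximum(self.bi, self.bj)
        self._excl_keys = np.unique(key)

        if config.pbc:
            if config.box is None:
                raise InvalidArgumentError("pbc requires a box")
            box = np.asarray(config.box, dtype=float)
            self.box = (np.diag(box).copy() if box.ndim == 2 else box.copy())
        else:
            self.box = np.zeros(3)
        self._pairs_built_at = None
        self._pi = self._pj = None

    # -- neighbour list ----------------------------------------------------
    def _build_pairs(self):
        rlist = self.config.lj_cutoff + self.config.neighbor_skin
        pos = self.pos
        if self.config.pbc:
            pos = np.mod(pos, self.box)
            tree = cKDTree(pos, boxsize=self.box)
        else:
            tree = cKDTree(pos)
        pairs = tree.query_pairs(r=rlist, output_type="ndarray")
        if len(pairs):
            keys = pairs[:, 0] * self.n + pairs[:, 1]
            keep = ~np.isin(keys, self._excl_keys)
            pairs = pairs[keep]
        self._pi = np.ascontiguousarray(pairs[:, 0]) if len(pairs) else np.empty(0, np.int64)
        self._pj = np.ascontiguousarray(pairs[:, 1]) if len(pairs) else np.empty(0, np.int64)
        ta = self.type_code[self._pi]
        tb = self.type_code[self._pj]
        self._psig = self._sig[ta, tb]
        self._peps = self._eps[ta, tb]
        self._pshift = self._vshift[ta, tb]
        self._pairs_built_at = self.pos.copy()

    def _maybe_rebuild(self):
        if self._pairs_built_at is None:
            self._build_pairs()
            return
        disp = np.abs(self.pos - self._pairs_built_at).max()
        if disp > 0.5 * self.config.neighbor_skin:
            self._build_pairs()

    # -- energy / forces ---------------------------------------------------
    def energy_forces(self) -> tuple[float, np.ndarray, dict]:
        """Total potential energy (kJ/mol), forces (kJ mol^-1 nm^-1), parts."""
        self._maybe_rebuild()
        forces = np.zeros_like(self.pos)
        e_bond = _kernels.bonded_energy_forces(
            self.pos, self.bi, self.bj, self.b0, self.bk,
            self.box, self.config.pbc, forces)
        e_lj = _kernels.lj_energy_forces(
            self.pos, self._pi, self._pj, self._psig, self._peps, self._pshift,
            self.config.lj_cutoff ** 2, self.box, self.config.pbc, forces)
        return e_bond + e_lj, forces, {"bond": e_bond, "lj": e_lj}


def total_energy_forces(model: FibrilModel, bonds: list[BondTerm],
                        nonbonded: NonbondedTable,
                        config: EngineConfig | None = None):
    """Energy (kJ/mol) and exact-gradient forces (kJ mol^-1 nm^-1)."""
    config = config or EngineConfig()
    system = System(model, bonds, nonbonded, config)
    e, f, parts = system.energy_forces()
    return e, f, parts


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def minimize(model: FibrilModel, bonds: list[BondTerm],
             nonbonded: NonbondedTable, config: EngineConfig | None = None,
             max_steps: int = 2000, fmax: float = 10.0,
             initial_step: float = 0.01):
    """Steepest-descent relaxation with adaptive step size.

    Stops when the largest force component drops below ``fmax``
    (kJ mol^-1 nm^-1) or after ``max_steps``.  The energy sequence is
    monotone non-increasing by construction.  Returns (relaxed model, info).
    """
    config = config or EngineConfig()
    system = System(model, bonds, nonbonded, config)
    e, forces, _ = system.energy_forces()
    if not math.isfinite(e):
        raise NumericalFailure("non-finite energy at start of minimization")
    step = initial_step
    n_eval = 1
    it = -1
    for it in range(max_steps):
        f_max = np.abs(forces).max() if len(forces) else 0.0
        if f_max < fmax:
            break
        trial = system.pos + step * forces / f_max
        saved = system.pos
        system.pos = trial
        e_t, f_t, _ = system.energy_forces()
        n_eval += 1
        if math.isnan(e_t):
            raise NumericalFailure(f"energy became NaN at minimization step {it}")
        if e_t < e:
            e, forces = e_t, f_t
            step = min(step * 1.2, 0.2)
        else:
            system.pos = saved
            step *= 0.5
            if step < 1e-10:
                break
    relaxed = model.with_positions(system.pos * A_PER_NM)
    info = {"energy": e, "max_force": float(np.abs(forces).max()),
            "steps": it + 1, "n_eval": n_eval}
    return relaxed, info


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _remove_com_velocity(vel, masses):
    p = (vel * masses[:, None]).sum(axis=0)
    vel -= p / masses.sum()


def _kinetic_energy(vel, masses):
    return 0.5 * float((masses[:, None] * vel * vel).sum())


def run_dynamics(model: FibrilModel, bonds: list[BondTerm],
                 nonbonded: NonbondedTable, config: EngineConfig,
                 n_steps: int, report_every: int = 100,
                 initial_velocities: np.ndarray | None = None) -> Trajectory:
    """NVT (or NVE) dynamics; returns a trajectory sampled every
    ``report_every`` steps (frame 0 is the initial state).

    Reproducible bit-for-bit for a fixed seed.  Centre-of-mass motion is
    removed throughout.  Raises :class:`NumericalFailure` naming the step
    on timestep instability (non-finite coordinates or energy blow-up).
    """
    if n_steps < 1:
        raise InvalidArgumentError("n_steps must be >= 1")
    system = System(model, bonds, nonbonded, config)
    n = system.n
    masses = system.masses
    inv_m = 1.0 / masses[:, None]
    dt = config.timestep
    kT = KB * config.temperature
    rng = np.random.default_rng(config.seed)

    vel = (initial_velocities.copy() if initial_velocities is not None
           else rng.standard_normal((n, 3)) * np.sqrt(kT / masses)[:, None])
    if config.temperature == 0.0 and initial_velocities is None:
        vel[:] = 0.0
    _remove_com_velocity(vel, masses)
    dof = max(3 * n - 3, 1)

    langevin = config.thermostat == "langevin"
    v_rescale = config.thermostat == "v_rescale"
    if langevin:
        c1 = math.exp(-config.friction * dt)
        c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
        sigma_v = np.sqrt(kT / masses)[:, None]

    e_pot, forces, _ = system.energy_forces()
    frames = [system.pos.copy() * A_PER_NM]
    times = [0.0]
    ke0 = _kinetic_energy(vel, masses)
    log = [{"step": 0, "time": 0.0, "potential": e_pot,
            "kinetic": ke0, "temperature": 2 * ke0 / (dof * KB)}]

    for step in range(1, n_steps + 1):
        # velocity half-kick, drift (B, A)
        vel += 0.5 * dt * forces * inv_m
        ke_half1 = _kinetic_energy(vel, masses)
        system.pos += 0.5 * dt * vel
        if langevin:  # O step (exact OU update)
            vel *= c1
            if config.temperature > 0:
                vel += c2 * sigma_v * rng.standard_normal((n, 3))
            _remove_com_velocity(vel, masses)
        system.pos += 0.5 * dt * vel
        ke_half2 = _kinetic_energy(vel, masses) if langevin else ke_half1
        try:
            e_pot, forces, _ = system.energy_forces()
        except ValueError as exc:
            raise NumericalFailure(
                f"timestep instability: non-finite coordinates at step {step}"
            ) from exc
        if not math.isfinite(e_pot):
            raise NumericalFailure(
                f"timestep instability: non-finite energy at step {step}")
        vel += 0.5 * dt * forces * inv_m
        if v_rescale:
            ke_on = _kinetic_energy(vel, masses)
            vel *= _bussi_factor(ke_on, dof, kT, dt, config.tau_t, rng)
            _remove_com_velocity(vel, masses)

        if step % report_every == 0 or step == n_steps:
            # kinetic energy from half-step velocities (leapfrog convention):
            # on-step estimates are biased low for the stiffest network modes
            # at this timestep.  v-rescale pins the on-step estimate instead.
            ke = (_kinetic_energy(vel, masses) if v_rescale
                  else 0.5 * (ke_half1 + ke_half2))
            if not math.isfinite(ke) or ke > 1e6 * max(dof * kT, 1.0):
                raise NumericalFailure(
                    f"timestep instability: energy blow-up at step {step}")
            frames.append(system.pos.copy() * A_PER_NM)
            times.append(step * dt)
            log.append({"step": step, "time": step * dt, "potential": e_pot,
                        "kinetic": ke, "temperature": 2 * ke / (dof * KB),
                        "kinetic_on_step": _kinetic_energy(vel, masses)})

    cfg = asdict(config)
    cfg["box"] = None if config.box is None else np.asarray(config.box).tolist()
    return Trajectory(
        times=np.array(times),
        coordinates=np.array(frames),
        box_vectors=model.box_vectors,
        metadata={"seed": config.seed, "config": cfg, "log": log,
                  "allomorph": model.allomorph},
    )


def _bussi_factor(ke, dof, kT, dt, tau, rng):
    """Stochastic velocity-rescaling factor (canonical-sampling thermostat)."""
    if ke <= 0 or kT <= 0:
        return 1.0
    c = math.exp(-dt / tau)
    ke_target = 0.5 * dof * kT
    r1 = rng.standard_normal()
    sum_r2 = rng.chisquare(dof - 1) if dof > 1 else 0.0
    alpha2 = (c + (1.0 - c) * ke_target * (r1 * r1 + sum_r2) / (dof * ke)
              + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ke_target / (dof * ke)))
    return math.sqrt(max(alpha2, 0.0))
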