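"""Reduced-scale reimplementation of the bead-type / elastic-constant scan.

The published model was selected by sweeping the 18 Martini 3 interaction
types for the oxygen-centred beads (the C6 bead held fixed at TC1) and
three elastic constants for the two flexible intra-residue bonds, scoring
each candidate by the time-averaged RMSD of short CG runs against a
reference structure, and keeping the candidate whose RMSD stays small for
all fibril systems simultaneously.  Only the published (sigma, epsilon)
subset ships with this package; the scan therefore takes a user-supplied
per-type parameter map for any other candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .builder import build_chain, build_fibril
from .engine import EngineConfig, run_dynamics, minimize
from .errors import MissingParameterError, NumericalFailure
from .analysis import traj_mean_rmsd
from .params import SCAN_BEAD_TYPES, SCAN_ELASTIC_CANDIDATES, mass_for_bead_type
from .topology import NonbondedTable, assign_bead_types, make_bond_terms

__all__ = ["ScanSpec", "scan", "rank_results", "select_best"]

_SOFT_PAIRS = {"O2-O6", "O3-O6"}


@dataclass
class ScanSpec:
    """Grid and protocol of the parameter scan.

    Defaults reproduce the published grid: 18 candidate interaction types
    x 3 elastic constants (25, 250, 2500 kJ mol^-1 nm^-2), scored on all
    three allomorphs.  ``cg3_type`` pins the C6 bead (set to None to scan
    it together with the oxygen beads).
    """

    candidate_types: tuple = SCAN_BEAD_TYPES
    elastic_candidates: tuple = SCAN_ELASTIC_CANDIDATES
    systems: tuple = ("Ialpha", "Ibeta", "II")
    cg3_type: str | None = "TC1"
    n_residues: int = 10
    n_chains: int = 1
    layout: tuple = (1, 1)
    n_steps: int = 5000
    equil_steps: int = 1000
    report_every: int = 50
    temperature: float = 300.0
    seed: int = 2022

    @property
    def grid_size(self) -> int:
        return len(self.candidate_types) * len(self.elastic_candidates)


def _candidate_system(spec: ScanSpec, allomorph: str, bead_type: str, k_soft: float):
    if spec.n_chains > 1:
        model = build_fibril(spec.n_chains, spec.layout, spec.n_residues, allomorph)
    else:
        model = build_chain(spec.n_residues, allomorph)
    model = assign_bead_types(model)
    # retype the oxygen beads with the candidate; CG3 optionally pinned
    types = np.where(model.bead_types == "SP6", bead_type, model.bead_types)
    if spec.cg3_type is not None:
        types = np.where(model.site_labels == "CG3", spec.cg3_type, types)
    else:
        types = np.where(model.site_labels == "CG3", bead_type, types)
    model.bead_types = types
    model.masses = np.array([mass_for_bead_type(t) for t in types])
    bonds = [replace(b, k=k_soft) if b.pair_label in _SOFT_PAIRS else b
             for b in make_bond_terms(model)]
    return model, bonds


def scan(spec: ScanSpec, nonbonded_source: NonbondedTable) -> pd.DataFrame:
    """Run the grid and return per-(type, k, system) scores.

    Columns: bead_type, k_soft, system, mean_rmsd, sd, status.  A grid
    point with no tabulated parameters is marked ``missing-parameters``; a
    diverging run is marked ``unstable``; either way the scan continues.
    Deterministic for a fixed spec seed.
    """
    rows = []
    for bead_type in spec.candidate_types:
        for k_soft in spec.elastic_candidates:
            for system_name in spec.systems:
                row = {"bead_type": bead_type, "k_soft": k_soft,
                       "system": system_name,
                       "mean_rmsd": np.nan, "sd": np.nan, "status": "ok"}
                try:
                    model, bonds = _candidate_system(
                        spec, system_name, bead_type, k_soft)
                    config = EngineConfig(temperature=spec.temperature,
                                          seed=spec.seed)
                    model, _ = minimize(model, bonds, nonbonded_source, config,
                                        max_steps=200)
                    traj = run_dynamics(model, bonds, nonbonded_source, config,
                                        n_steps=spec.equil_steps + spec.n_steps,
                                        report_every=spec.report_every)
                    start = spec.equil_steps // spec.report_every
                    prod = traj.sliced(start=start)
                    mean, sd, _ = traj_mean_rmsd(prod, reference=prod.frame(0))
                    row.update(mean_rmsd=mean, sd=sd)
                except MissingParameterError:
                    row["status"] = "missing-parameters"
                except NumericalFailure:
                    row["status"] = "unstable"
                rows.append(row)
    return pd.DataFrame(rows)


def rank_results(results: pd.DataFrame, aggregate: str = "max") -> pd.DataFrame:
    """Aggregate per-system scores and rank candidates.

    The selection criterion is simultaneous smallness: by default a
    candidate's score is its maximum mean RMSD over the systems (``mean``
    aggregation available).  Candidates with any failed system are
    excluded from the ranking.  Pure: re-ranking a saved table gives the
    same answer.
    """
    ok = results.groupby(["bead_type", "k_soft"]).filter(
        lambda g: (g["status"] == "ok").all())
    if ok.empty:
        return pd.DataFrame(columns=["bead_type", "k_soft", "score", "rank"])
    agg = getattr(ok.groupby(["bead_type", "k_soft"])["mean_rmsd"], aggregate)()
    table = agg.reset_index().rename(columns={"mean_rmsd": "score"})
    table = table.sort_values(["score", "bead_type", "k_soft"],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def select_best(results: pd.DataFrame, aggregate: str = "max"):
    """(bead_type, k_soft) of the top-ranked candidate, or None if all failed."""
    ranked = rank_results(results, aggregate=aggregate)
    if ranked.empty:
        return None
    top = ranked.iloc[0]
    return str(top["bead_type"]), float(top["k_soft"])
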