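"""Bead typing, bonded terms, the nonbonded matrix, and topology files.

The published parameter set assigns Martini 3 bead type TC1 to the
C6-centred bead (CG3) and SP6 to the three oxygen-centred beads (CG1, CG2,
CG4).  Bonded terms are harmonic springs on the chain triangulation; the
nonbonded matrix is an exact tabulated Lennard-Jones matrix with no
combining rules.  Files are written in a GROMACS .itp/.top dialect
(nm / kJ mol^-1 units) and can be read back by this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from .builder import FibrilModel, sch_connectivity
from .errors import InvalidModelError, MissingParameterError, ParseError
from .params import (
    BEAD_CHARGES,
    BEAD_MASSES,
    NM_PER_A,
    NONBONDED_PARAMS,
    SITE_TO_ATOM,
    SITE_TO_BEAD_TYPE,
    bonded_lookup,
    mass_for_bead_type,
)

__all__ = [
    "BondTerm",
    "NonbondedTable",
    "assign_bead_types",
    "make_bond_terms",
    "nonbonded_lookup",
    "write_topology",
    "read_topology",
]


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond V = 1/2 k (r - r0)^2; r0 in Å, k in kJ mol^-1 nm^-2."""

    i: int
    j: int
    r0: float
    k: float
    neighbour_class: str  # intra | first | second
    pair_label: str       # e.g. "O2-O6"

    def __post_init__(self):
        if self.r0 <= 0 or self.k <= 0:
            raise InvalidModelError("bond term requires r0 > 0 and k > 0")


class NonbondedTable:
    """Symmetric (type, type) -> (sigma Å, epsilon kJ/mol) map.

    Only explicitly tabulated pairs resolve; there are no combining rules,
    so looking up an absent pair raises :class:`MissingParameterError`.
    Charges default to zero for every known type.
    """

    def __init__(self, entries=None, charges=None):
        self._entries: dict[frozenset, tuple[float, float]] = {}
        self.charges: dict[str, float] = dict(charges or {})
        for key, (sigma, eps) in (entries or {}).items():
            pair = tuple(key) if not isinstance(key, frozenset) else tuple(key)
            if len(pair) == 1:
                pair = (pair[0], pair[0])
            self.add(pair[0], pair[1], sigma, eps)

    @classmethod
    def martini_cellulose(cls) -> "NonbondedTable":
        """The published five-pair matrix (SP6/TC1 plus W cross terms)."""
        table = cls()
        for key, (sigma, eps) in NONBONDED_PARAMS.items():
            pair = tuple(key)
            a = pair[0]
            b = pair[1] if len(pair) > 1 else pair[0]
            table.add(a, b, sigma, eps)
        for t in table.types:
            table.charges.setdefault(t, 0.0)
        return table

    # -- mapping interface -------------------------------------------------
    @property
    def types(self) -> list[str]:
        out = set()
        for key in self._entries:
            out.update(key)
        return sorted(out)

    def add(self, a: str, b: str, sigma: float, epsilon: float) -> None:
        self._entries[frozenset({a, b})] = (float(sigma), float(epsilon))

    def lookup(self, a: str, b: str) -> tuple[float, float]:
        """(sigma Å, epsilon kJ/mol); order-independent, exact pairs only."""
        try:
            return self._entries[frozenset({a, b})]
        except KeyError:
            raise MissingParameterError(
                f"no nonbonded parameters tabulated for pair ({a}, {b})") from None

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self._entries

    def items(self):
        for key, val in sorted(self._entries.items(),
                               key=lambda kv: sorted(kv[0])):
            pair = sorted(key)
            yield (pair[0], pair[-1]), val

    def __eq__(self, other):
        return (isinstance(other, NonbondedTable)
                and self._entries == other._entries
                and self.charges == other.charges)


def nonbonded_lookup(a: str, b: str,
                     table: NonbondedTable | None = None) -> tuple[float, float]:
    """Symmetric exact lookup in the published matrix (or a supplied table)."""
    table = table if table is not None else NonbondedTable.martini_cellulose()
    return table.lookup(a, b)


def assign_bead_types(model: FibrilModel) -> FibrilModel:
    """Return a typed copy: CG3 -> TC1; CG1, CG2, CG4 -> SP6.

    Masses are the standard Martini 3 small/tiny bead masses and all
    charges are zero (no charged cellulose beads).
    """
    unknown = set(np.unique(model.site_labels)) - set(SITE_TO_BEAD_TYPE)
    if unknown:
        raise InvalidModelError(f"unknown site label(s): {sorted(unknown)}")
    bead_types = np.array([SITE_TO_BEAD_TYPE[s] for s in model.site_labels])
    typed = replace(
        model,
        positions=model.positions.copy(),
        bead_types=bead_types,
        masses=np.array([BEAD_MASSES[t] for t in bead_types]),
        charges=np.array([BEAD_CHARGES[t] for t in bead_types]),
    )
    return typed


def make_bond_terms(model: FibrilModel) -> list[BondTerm]:
    """One harmonic term per triangulation pair, parameters from the table.

    Bonds are intra-chain only: chains interact solely through nonbonded
    terms.  A pair with no tabulated parameters raises
    :class:`MissingParameterError`.
    """
    terms = []
    for i, j, cls, lbl in sch_connectivity(model):
        try:
            r0, k = bonded_lookup(cls, lbl)
        except KeyError:
            raise MissingParameterError(
                f"no bonded parameters for ({lbl}, {cls})") from None
        terms.append(BondTerm(i=i, j=j, r0=r0, k=k,
                              neighbour_class=cls, pair_label=lbl))
    return terms


# ---------------------------------------------------------------------------
# GROMACS-dialect topology files
# ---------------------------------------------------------------------------

_MOLECULE_NAME = "CELLULOSE_CG"


def write_topology(model: FibrilModel, bonds: list[BondTerm],
                   nonbonded: NonbondedTable, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.itp`` and ``<prefix>.top`` (nm, kJ/mol units).

    The .itp carries [atomtypes], [nonbond_params], [moleculetype], [atoms],
    [bonds] and [exclusions]; every bonded pair is excluded from nonbonded
    interactions (stiff-bond pairs sit far below sigma).  Round-trips
    through :func:`read_topology`.
    """
    if model.bead_types is None:
        raise InvalidModelError("model is untyped; run assign_bead_types first")
    itp_path = f"{prefix}.itp"
    top_path = f"{prefix}.top"

    lines = ["; cgfibril topology — 4-bead Martini 3 cellulose model", ""]
    lines.append("[ atomtypes ]")
    lines.append("; name  mass    charge  ptype")
    for t in nonbonded.types:
        mass = mass_for_bead_type(t)
        q = nonbonded.charges.get(t, 0.0)
        lines.append(f"{t:<6s} {mass:8.3f} {q:8.3f}  A")
    lines.append("")
    lines.append("[ nonbond_params ]")
    lines.append("; i      j      func  sigma(nm)   epsilon(kJ/mol)")
    for (a, b), (sigma, eps) in nonbonded.items():
        lines.append(f"{a:<6s} {b:<6s} 1  {sigma * NM_PER_A:10.5f}  {eps:10.5f}")
    lines.append("")
    lines.append("[ moleculetype ]")
    lines.append("; name         nrexcl")
    lines.append(f"{_MOLECULE_NAME}   1")
    lines.append("")
    lines.append("[ atoms ]")
    lines.append("; nr  type  resnr  residue  atom  cgnr  charge  mass")
    for idx in range(model.n_beads):
        atom = SITE_TO_ATOM[str(model.site_labels[idx])]
        q = 0.0 if model.charges is None else float(model.charges[idx])
        lines.append(
            f"{idx + 1:6d}  {model.bead_types[idx]:<5s} "
            f"{int(model.residue_indices[idx]) + 1:5d}  BGC   {atom:<4s} "
            f"{idx + 1:6d}  {q:7.3f}  {float(model.masses[idx]):8.3f}")
    lines.append("")
    lines.append("[ bonds ]")
    lines.append("; i      j      func  b0(nm)      kb(kJ/mol/nm^2) ; class label")
    for b in bonds:
        lines.append(
            f"{b.i + 1:6d} {b.j + 1:6d} 1  {b.r0 * NM_PER_A:10.5f}  "
            f"{b.k:12.1f} ; {b.neighbour_class} {b.pair_label}")
    lines.append("")
    lines.append("[ exclusions ]")
    for b in bonds:
        lines.append(f"{b.i + 1:6d} {b.j + 1:6d}")
    lines.append("")
    with open(itp_path, "w") as fh:
        fh.write("\n".join(lines))

    with open(top_path, "w") as fh:
        fh.write(
            f'#include "{itp_path}"\n\n'
            "[ system ]\n"
            f"CG cellulose {model.allomorph} fibril\n\n"
            "[ molecules ]\n"
            f"{_MOLECULE_NAME}  1\n"
        )
    return itp_path, top_path


def read_topology(prefix_or_itp: str):
    """Parse a topology written by :func:`write_topology`.

    Returns a dict with keys ``atoms`` (list of (type, residue_index,
    atom_name, charge, mass)), ``bonds`` (list of :class:`BondTerm`, r0
    converted back to Å), ``nonbonded`` (:class:`NonbondedTable`, sigma in
    Å) and ``exclusions`` (list of (i, j), 0-based).
    """
    path = prefix_or_itp if prefix_or_itp.endswith(".itp") else prefix_or_itp + ".itp"
    section = None
    atoms, bonds, exclusions = [], [], []
    table = NonbondedTable()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            m = re.match(r"\[\s*(\S+)\s*\]", line)
            if m:
                section = m.group(1)
                continue
            fields = line.split()
            try:
                if section == "atomtypes":
                    table.charges[fields[0]] = float(fields[2])
                elif section == "nonbond_params":
                    # nm -> Å, rounded at file precision to keep exact values
                    table.add(fields[0], fields[1],
                              round(float(fields[3]) / NM_PER_A, 6),
                              float(fields[4]))
                elif section == "atoms":
                    atoms.append((fields[1], int(fields[2]) - 1, fields[4],
                                  float(fields[6]), float(fields[7])))
                elif section == "bonds":
                    comment = raw.split(";", 1)[1].split() if ";" in raw else ["?", "?"]
                    bonds.append(BondTerm(
                        i=int(fields[0]) - 1, j=int(fields[1]) - 1,
                        r0=float(fields[3]) / NM_PER_A, k=float(fields[4]),
                        neighbour_class=comment[0], pair_label=comment[1]))
                elif section == "exclusions":
                    exclusions.append((int(fields[0]) - 1, int(fields[1]) - 1))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed record: {raw!r}") from exc
    return {"atoms": atoms, "bonds": bonds, "nonbonded": table,
            "exclusions": exclusions}
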