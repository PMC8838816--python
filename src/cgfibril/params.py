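"""Published force-field constants for the 4-bead cellulose model.

The model maps each D-glucose residue onto four coarse-grained beads centred
on the O2, O3, C6 and O6 atoms (CG1..CG4).  Bonded terms form an elastic
network covering the flat ribbon of a cellulose chain; nonbonded terms are
Lennard-Jones (12-6) interactions between Martini 3 bead types.  All values
here are the optimal published parameter set; they are shared by the Ialpha,
Ibeta and type-II allomorphs (the bonded model is transferable).
"""

from __future__ import annotations

ALLOMORPHS = ("Ialpha", "Ibeta", "II")

SITE_LABELS = ("CG1", "CG2", "CG3", "CG4")

#: fixed bijection between CG site labels and their source atoms
SITE_TO_ATOM = {"CG1": "O2", "CG2": "O3", "CG3": "C6", "CG4": "O6"}
ATOM_TO_SITE = {v: k for k, v in SITE_TO_ATOM.items()}

#: Martini 3 bead type per CG site: the C6-centred bead is tiny-apolar TC1,
#: the three oxygen-centred beads are small-polar SP6.
SITE_TO_BEAD_TYPE = {"CG1": "SP6", "CG2": "SP6", "CG3": "TC1", "CG4": "SP6"}

#: standard Martini 3 masses (amu) for small (S) and tiny (T) beads
BEAD_MASSES = {"SP6": 54.0, "TC1": 36.0}

#: all cellulose beads are uncharged
BEAD_CHARGES = {"SP6": 0.0, "TC1": 0.0}

# ---------------------------------------------------------------------------
# Bonded elastic network: (neighbour_class, pair_label) -> (r0 [Å], k [kJ mol^-1 nm^-2])
# neighbour_class: "intra" (within one residue), "first"/"second" (between
# residues i and i+1 / i+2 of the same chain).  Only the two flexible
# intra-residue distances O2-O6 and O3-O6 use the soft 2500 constant; every
# bell-shaped distance uses 30,000.
# ---------------------------------------------------------------------------
BONDED_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("intra", "O2-O3"): (2.88, 30000.0),
    ("intra", "O2-C6"): (5.62, 30000.0),
    ("intra", "O3-C6"): (4.94, 30000.0),
    ("intra", "C6-O6"): (1.43, 30000.0),
    ("intra", "O2-O6"): (6.42, 2500.0),
    ("intra", "O3-O6"): (5.76, 2500.0),
    ("first", "O2-O2"): (7.56, 30000.0),
    ("first", "O3-O3"): (6.69, 30000.0),
    ("first", "C6-C6"): (7.47, 30000.0),
    ("second", "O2-O2"): (10.44, 30000.0),
    ("second", "O3-O3"): (10.44, 30000.0),
    ("second", "C6-C6"): (10.44, 30000.0),
}

#: intra-residue pair labels in canonical order
INTRA_PAIRS = ("O2-O3", "O2-C6", "O3-C6", "C6-O6", "O2-O6", "O3-O6")
#: atoms carrying inter-residue (1st and 2nd neighbour) elastic bonds; O6 has none
INTER_ATOMS = ("O2", "O3", "C6")

# ---------------------------------------------------------------------------
# Nonbonded Lennard-Jones matrix: unordered pair of bead types -> (sigma [Å],
# epsilon [kJ/mol]).  Only the published pairs are present; there are no
# combining rules — looking up an absent pair is an error.  W is Martini
# water (cross terms stored for completeness; W-W itself is not published).
# ---------------------------------------------------------------------------
NONBONDED_PARAMS: dict[frozenset, tuple[float, float]] = {
    frozenset({"W", "SP6"}): (4.250, 4.530),
    frozenset({"SP6"}): (4.100, 4.290),
    frozenset({"W", "TC1"}): (4.150, 0.550),
    frozenset({"TC1"}): (3.400, 1.510),
    frozenset({"SP6", "TC1"}): (4.840, 0.890),
}

#: the 18 Martini 3 interaction types scanned during parameterization
SCAN_BEAD_TYPES = (
    "P1", "P6", "SP1", "SP6", "TP1", "TP6",
    "N1", "N6", "SN1", "SN6", "TN1", "TN6",
    "C1", "C6", "SC1", "SC6", "TC1", "TC6",
)

#: elastic constants scanned for the flexible O2-O6 / O3-O6 bonds (kJ mol^-1 nm^-2)
SCAN_ELASTIC_CANDIDATES = (25.0, 250.0, 2500.0)

# unit conversions and physical constants
A_PER_NM = 10.0
NM_PER_A = 0.1
KB = 0.008314462618  # kJ mol^-1 K^-1


def mass_for_bead_type(bead_type: str) -> float:
    """Standard Martini 3 mass (amu) by bead size class (T=36, S=54, else 72)."""
    if bead_type in BEAD_MASSES:
        return BEAD_MASSES[bead_type]
    if bead_type.startswith("T"):
        return 36.0
    if bead_type.startswith("S"):
        return 54.0
    return 72.0


def bonded_lookup(neighbour_class: str, pair_label: str) -> tuple[float, float]:
    """Return (r0 [Å], k [kJ mol^-1 nm^-2]) for a bonded pair class.

    Raises KeyError for a pair with no published parameters.
    """
    key = (neighbour_class, pair_label)
    if key not in BONDED_PARAMS:
        # pair labels are unordered: try the swapped form
        a, _, b = pair_label.partition("-")
        key = (neighbour_class, f"{b}-{a}")
    return BONDED_PARAMS[key]
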