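"""Exception hierarchy used across the package."""


class CgFibrilError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CgFibrilError, ValueError):
    """An operation was called with out-of-contract arguments."""


class InvalidModelError(CgFibrilError, ValueError):
    """A structural model violates its invariants (bad site label, untyped, ...)."""


class MappingError(CgFibrilError, ValueError):
    """An atomistic structure cannot be mapped onto the 4-bead representation."""


class MissingParameterError(CgFibrilError, LookupError):
    """A bonded or nonbonded parameter was requested that is not tabulated."""


class ParseError(CgFibrilError, ValueError):
    """A structure/topology file could not be parsed."""


class FormatError(CgFibrilError, ValueError):
    """A trajectory or file is structurally inconsistent (e.g. atom count changes)."""


class NumericalFailure(CgFibrilError, RuntimeError):
    """Minimization or dynamics diverged (NaN / energy blow-up)."""


class UndefinedDihedralError(CgFibrilError, ValueError):
    """A dihedral angle is undefined because of collinear points."""
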