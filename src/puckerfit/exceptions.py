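"""Exception and warning types shared across the package."""


class PuckerfitError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(PuckerfitError):
    """Raised when a dihedral is requested for collinear/coincident points."""


class MissingAtomError(PuckerfitError):
    """Raised when a required ring atom is absent from a residue."""


class ResidueNotFoundError(PuckerfitError):
    """Raised when a residue selector matches no residue in a model."""


class StructureParseError(PuckerfitError):
    """Raised for unreadable/empty/malformed structure or table files."""


class SchemeError(PuckerfitError):
    """Raised for malformed pucker classification schemes."""


class InsufficientDataError(PuckerfitError):
    """Raised when a dataset has too few points to support a fit."""


class FitConvergenceError(PuckerfitError):
    """Raised when a nonlinear fit fails to converge."""


class DataQualityWarning(UserWarning):
    """Warns about suspicious but usable input (bond lengths, altlocs...)."""


class UnidentifiableFitWarning(UserWarning):
    """Warns when the experimental design cannot constrain a parameter."""
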