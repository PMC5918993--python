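"""Exception hierarchy.

Every error raised by trajkit derives from :class:`TrajkitError`, so callers
(and the CLI) can distinguish validation problems from genuine bugs.
"""


class TrajkitError(Exception):
    """Base class for all trajkit errors."""


class PDBParseError(TrajkitError):
    """A coordinate file could not be parsed; the message names the line."""


class TopologyError(TrajkitError):
    """Atom tables of two objects (or MODEL blocks) do not match."""


class LookupError_(TrajkitError):
    """A mass or radius could not be assigned to an atom."""


class SelectionError(TrajkitError):
    """A selection resolved to nothing (and allow_empty was not set)."""


class SelectionSyntaxError(SelectionError):
    """A selection expression could not be parsed; names the bad token."""


class RangeError(TrajkitError):
    """A frame range / discard request exceeds the trajectory length."""


class GeometryError(TrajkitError):
    """Too few or degenerate coordinates for a geometric fit."""


class ConvergenceError(TrajkitError):
    """An iterative procedure failed to converge; message reports the last shift."""


class DataError(TrajkitError):
    """Not enough data for the requested statistic (e.g. < 2 frames)."""


class UndefinedGapIndexError(TrajkitError):
    """Gap index requested but the buried area is below the definedness threshold."""


class ContactSpecError(TrajkitError):
    """A contact criterion cannot be evaluated on the given selections."""


class ConfigError(TrajkitError):
    """Invalid generator or pipeline configuration."""


class MappingError(TrajkitError):
    """Residue sets of two systems cannot be put in correspondence."""


class ConstructionError(TrajkitError):
    """Synthetic-structure construction produced a steric clash."""
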