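"""Exception hierarchy.

Every error the package raises deliberately derives from
:class:`ScassignError`, so callers (and the CLI) can catch one base class
and map each subclass to a stable diagnostic.
"""


class ScassignError(Exception):
    """Base class for all errors raised by scassign."""


class NameCollisionError(ScassignError):
    """A classifier with the same cell-type name already exists."""


class UnresolvedParentError(ScassignError):
    """A classifier references a parent that is not in the database."""


class NotFoundError(ScassignError):
    """A requested cell type / entry does not exist."""


class DatabaseValidationError(ScassignError):
    """The classifier database violates its forest invariants."""


class VersionError(ScassignError):
    """An archive declares an unsupported format version."""


class ArchiveParseError(ScassignError):
    """An archive is malformed; the message names the offending field."""


class FormatError(ScassignError):
    """An input file does not match its declared format."""


class DegenerateCellError(ScassignError):
    """One or more cells have zero total counts."""


class EmptyOverlapError(ScassignError):
    """None of the requested features are present in the matrix."""


class ShapeError(ScassignError):
    """Array lengths or shapes are inconsistent."""


class DegenerateLabelsError(ScassignError):
    """Binary labeling produced a single class."""


class SampleSizeError(ScassignError):
    """Too few cells per class to train."""


class DegenerateFeaturesError(ScassignError):
    """All candidate features are constant on the training cells."""


class OptimizationError(ScassignError):
    """An iterative fit failed to converge."""


class ValidityError(ScassignError):
    """A parameter is outside its valid range."""


class InfeasibleError(ScassignError):
    """The requested operating point cannot be reached."""


class AlignmentError(ScassignError):
    """Two per-cell tables do not cover the same cells."""


class SimulationSpecError(ScassignError):
    """A simulation specification violates its constraints."""


class StratificationError(ScassignError):
    """A class is too small for a stratified split."""
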