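"""Exception hierarchy shared across the toolkit."""


class HicCuratorError(Exception):
    """Base class for all package errors."""


class FormatError(HicCuratorError):
    """Malformed on-disk input (archive manifest, assembly text, table)."""


class IntegrityError(HicCuratorError):
    """Stored data violates a structural invariant (shape, symmetry)."""


class ParameterError(HicCuratorError, ValueError):
    """Invalid argument value."""


class BoundsError(HicCuratorError, IndexError):
    """Coordinate outside the genome or assembly."""


class NoInsertionSiteError(HicCuratorError):
    """The peak algorithm found no candidate insertion site; the call is skipped."""


class AssignmentError(HicCuratorError):
    """Chromosome assignment could not be performed (no chromosome boxes)."""


class CorrectionStalled(HicCuratorError):
    """Iterative correction made no progress for ``stall_patience`` iterations."""


class ReferenceResolutionError(HicCuratorError, KeyError):
    """A fragment name could not be resolved to a contig slice."""
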