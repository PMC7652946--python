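"""Exception hierarchy for texrobust.

All package-specific failures derive from :class:`TexRobustError` so callers
can catch one base class; subclasses mirror the pipeline stages where a
contract can be violated.
"""


class TexRobustError(Exception):
    """Base class for all texrobust errors."""


class DomainError(TexRobustError, ValueError):
    """An argument violates a documented precondition (empty mask,
    non-positive spacing, degenerate parameter range, ...)."""


class SizingError(DomainError):
    """A synthetic lesion does not fit in the requested grid."""


class PerturbationError(TexRobustError):
    """A simulated reader perturbation emptied or fragmented the mask."""


class AlignmentError(TexRobustError):
    """A labelmap's grid shape or spacing does not match its parent volume."""


class DegenerateMatrixError(TexRobustError):
    """A texture matrix cannot be built (e.g. single-voxel ROI with no
    co-occurring pairs)."""


class PairingError(TexRobustError):
    """Paired per-lesion inputs have mismatched lengths."""
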