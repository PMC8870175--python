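"""Exception hierarchy for the ramelan pipeline."""


class RamelanError(Exception):
    """Base class for all ramelan errors."""


class FormatError(RamelanError):
    """Malformed on-disk artifact (axis not increasing, bad header, ...)."""


class ParseError(FormatError):
    """Non-numeric cell or unreadable value; message carries row/column."""


class ConsistencyError(RamelanError):
    """Internally inconsistent inputs (meta/matrix mismatch, misaligned scores)."""


class LatticeError(RamelanError):
    """Map pixel coordinates do not form a complete rectangular grid."""


class ConfigurationError(RamelanError):
    """Invalid parameter value or combination."""


class DespikeError(RamelanError):
    """Cosmic-ray removal flagged essentially every channel."""


class CorrectionError(RamelanError):
    """Scatter correction failed for a spectrum (degenerate regression)."""


class ExtractionError(RamelanError):
    """No MCR component resembles the requested background signature."""


class FitError(RamelanError):
    """Numerical failure while fitting a model."""


class AssignmentError(RamelanError):
    """Component-to-pigment assignment impossible on this axis or result."""


class StatTestError(RamelanError):
    """Degenerate statistical test input."""


class ColocalizationError(RamelanError):
    """Invalid image pair for colocalization (zero variance, shape mismatch)."""


class CVError(RamelanError):
    """Cross-validation split lost a class or is otherwise infeasible."""
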