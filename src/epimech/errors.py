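"""Exception hierarchy.

Validation/format problems map to CLI exit code 2, fit failures to 3.
"""


class EpimechError(Exception):
    """Base class for all epimech errors."""

    exit_code = 1


class FormatError(EpimechError):
    """A file does not conform to its documented schema."""

    exit_code = 2


class ValidationError(EpimechError):
    """Input data violate a physical or structural invariant."""

    exit_code = 2


class DomainError(ValidationError):
    """A scalar argument lies outside the physically meaningful domain."""


class SignConventionError(ValidationError):
    """A phase-frequency slope has the wrong sign for the stated convention."""


class ExtractionError(EpimechError):
    """A per-sweep quantity (e.g. the pi/2-phase frequency) could not be extracted."""

    exit_code = 2


class InsufficientDataError(ExtractionError):
    """Too few samples inside the fit window."""


class PeakNotFoundError(ExtractionError):
    """No amplitude resonance peak inside the search window."""


class VertexNotFoundError(ExtractionError):
    """An intensity profile lacks the two opposite-sign derivative extrema."""


class FitError(EpimechError):
    """A nonlinear least-squares fit failed to converge."""

    exit_code = 3


class DegenerateDataError(FitError):
    """Data carry no signal for the requested fit (e.g. all-zero frequency shifts)."""


class ContactNotFoundError(FitError):
    """A force curve shows no detectable contact regime."""


class ConfigError(EpimechError):
    """An inconsistent simulation or analysis configuration."""

    exit_code = 2
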