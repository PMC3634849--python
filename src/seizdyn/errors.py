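"""Exception hierarchy used across the package."""


class SeizdynError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SeizdynError):
    """A file or table does not conform to the expected layout."""


class ParameterError(SeizdynError, ValueError):
    """An argument is outside its valid domain."""


class PreconditionError(SeizdynError):
    """Input data do not satisfy an operation's requirements."""


class DegenerateSignalError(SeizdynError):
    """The signal is degenerate for the requested feature (e.g. flat)."""


class AlignmentError(SeizdynError):
    """Inputs are not on a common time grid."""
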