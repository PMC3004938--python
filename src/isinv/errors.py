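"""Exception types raised by the isinv pipeline."""


class IsinvError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IsinvError, ValueError):
    """A configuration or element specification is internally inconsistent."""


class FormatError(IsinvError, ValueError):
    """An input file violates its format contract (ragged alignment, ...)."""


class MalformedElementError(IsinvError, ValueError):
    """An element sequence is too short or structurally invalid for an operation."""


class MalformedInputError(IsinvError, ValueError):
    """A sequence argument violates an operation's precondition."""


class UnknownStrainError(IsinvError, LookupError):
    """A strain id was not found in the alignment or tree."""


class ReconciliationError(IsinvError, ValueError):
    """Tree leaves and state-table strains do not match."""


class NoDiagnosticAsymmetryError(IsinvError, ValueError):
    """The canonical TIR pair lacks the single diagnostic mismatch required
    for mechanism classification."""
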