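"""Exception hierarchy shared across the package."""


class SleepCortexError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SleepCortexError, ValueError):
    """Malformed input file (bad token, gap in epoch numbering, ...)."""


class SpecError(SleepCortexError, ValueError):
    """Invalid simulation or run specification."""


class InsufficientDataError(SleepCortexError):
    """No eligible data for a requested computation (e.g. zero artifact-free
    windows in a state)."""


class DegenerateInputError(SleepCortexError, ValueError):
    """Input that makes the computation undefined (zero variance, zero total
    power, ...)."""


class ReconciliationError(SleepCortexError, ValueError):
    """Subject sets of two input tables do not match."""
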