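"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigurationError/InputError -> 2,
FittingError/NumericalError -> 3.
"""


class ExpowinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExpowinError):
    """A run or generator configuration field is invalid."""


class InputError(ExpowinError):
    """An input table or value violates its contract."""


class FittingError(ExpowinError):
    """A statistical model could not be fitted."""


class NumericalError(ExpowinError):
    """A numerical routine failed (singularity, non-convergence)."""


class SizeError(ExpowinError):
    """An exact computation was requested above its state-space limits."""
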