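"""Exception hierarchy.

Validation/configuration problems (bad user input) are distinguished from
computation failures so the CLI can map them to distinct exit codes.
"""


class KarstBetaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KarstBetaError):
    """Invalid configuration (incompatible grain, non-divisible extent, ...)."""


class FormatError(KarstBetaError):
    """Malformed input file (missing columns, unreadable CSV)."""


class ValidationError(KarstBetaError):
    """Input data violate a stated invariant (out-of-bounds stem, duplicate tag)."""


class ComputationError(KarstBetaError):
    """A numerical stage cannot produce a defined result (degenerate input)."""
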