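"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: usage/configuration problems exit
with 2, malformed or inconsistent data with 3, anything else with 4.
"""


class EcrestrictError(Exception):
    """Base class for all errors raised by this package."""


class UsageError(EcrestrictError):
    """A function was called with arguments that make no sense
    (empty sample group, unknown subgroup, non-positive fold, ...)."""


class ConfigError(UsageError):
    """An invalid simulation or pipeline configuration."""


class DataFormatError(EcrestrictError):
    """A file or in-memory table violates a format or type invariant."""
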