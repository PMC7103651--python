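"""Exception hierarchy shared across the package.

Everything user-facing derives from :class:`IcpscreenError` so the CLI can
map any validation/parse failure to a single exit code.
"""


class IcpscreenError(Exception):
    """Base class for all icpscreen errors."""


class ParseError(IcpscreenError):
    """A text input could not be parsed into a valid table."""


class ValidationError(IcpscreenError):
    """An in-memory object violates one of its invariants."""


class ConfigError(IcpscreenError):
    """A run configuration value is out of its admissible range."""


class StratumMismatchError(IcpscreenError):
    """Two stage artifacts were computed on different strata."""
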