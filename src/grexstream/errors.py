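"""Exception hierarchy.

All anticipated failure modes raise a :class:`GrexStreamError` subclass so the
CLI can map them to a single-line cause and a nonzero exit status.
"""


class GrexStreamError(Exception):
    """Base class for all grexstream errors."""


class ConfigError(GrexStreamError):
    """Invalid user configuration: missing columns, bad paths, bad options."""


class FormatError(GrexStreamError):
    """Malformed input or output file content."""


class DataError(GrexStreamError):
    """Inconsistent data: duplicate identifiers, mismatched manifests."""


class ContractError(GrexStreamError):
    """Internal contract violated (lifecycle bugs, out-of-range reads)."""
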