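"""Exception hierarchy shared across the package.

All errors derive from :class:`ReachkinError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
bad arguments/configuration, malformed files, and degenerate signals.
"""


class ReachkinError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ReachkinError, ValueError):
    """Invalid argument, configuration value, or inconsistent metadata."""


class FormatError(ReachkinError, ValueError):
    """A file exists but does not parse as the expected format."""


class SchemaError(ReachkinError, KeyError):
    """An identifier (series name, feature column, marker) is unknown."""


class DegenerateInputError(ReachkinError, ValueError):
    """A signal is degenerate for the requested operation (e.g. constant
    vertical fingertip coordinate, which leaves the crop threshold undefined)."""


class NoMovementError(DegenerateInputError):
    """No sample ever exceeds the lift-detection threshold."""
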