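"""Exception hierarchy.

All validation problems raise :class:`SodscreenError` subclasses so callers
(and the CLI, which maps them to exit code 2) can distinguish bad input from
genuine bugs.
"""


class SodscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SodscreenError, ValueError):
    """A numeric input was missing, non-finite, or out of its valid range."""


class DegenerateFitError(SodscreenError, ValueError):
    """A regression was requested on data that cannot determine a line."""


class InvalidTableError(SodscreenError, ValueError):
    """A materials table violates structural requirements (empty, duplicate ids)."""


class FormatError(SodscreenError, ValueError):
    """A file does not conform to the expected on-disk format."""
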