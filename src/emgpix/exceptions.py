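"""Exception hierarchy.

All errors derive from :class:`EmgpixError` and, where sensible, from the
built-in exception a caller would naturally catch (``ValueError``), so the
package composes with generic error handling.
"""


class EmgpixError(Exception):
    """Base class for all package errors."""


class ParameterError(EmgpixError, ValueError):
    """An invalid parameter value (filter cutoffs, sampling rate, ...)."""


class DomainError(EmgpixError, ValueError):
    """A value outside its documented domain (gesture id, channel count)."""


class DataError(EmgpixError, ValueError):
    """Malformed data content (non-finite samples, bad pixel values)."""


class DimensionError(EmgpixError, ValueError):
    """An array whose shape violates an operation's contract."""


class ConfigError(EmgpixError, ValueError):
    """An invalid run configuration (unknown keys, inconsistent sections)."""


class IntegrityError(EmgpixError, ValueError):
    """A file whose header and payload disagree."""


class ParseError(EmgpixError, ValueError):
    """A file that cannot be parsed at all."""
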