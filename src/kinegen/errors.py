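"""Exception hierarchy.

Every error raised by kinegen derives from :class:`KinegenError`, so callers
can catch one type at pipeline level while tests assert on the specific
subclass.
"""


class KinegenError(Exception):
    """Base class for all kinegen errors."""


class FormatError(KinegenError):
    """A file does not follow the documented dialect (bad header, bad row)."""


class ValidationError(KinegenError):
    """A table violates its vocabulary or uniqueness constraints."""


class ConfigError(KinegenError):
    """A simulation or study configuration is physically or logically invalid."""


class ParameterError(KinegenError):
    """An analysis parameter is out of its admissible range."""


class InputError(KinegenError):
    """An input series/marker set is unusable (too short, marker missing)."""


class DegenerateGeometryError(KinegenError):
    """Coincident markers make a joint angle undefined; carries the frame index."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class SegmentationError(KinegenError):
    """An expected movement phase could not be located in a trial."""


class DomainError(KinegenError):
    """A formula was called outside its mathematical domain."""
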