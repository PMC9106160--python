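"""Exception hierarchy for gaitevents."""


class GaitEventsError(Exception):
    """Base class for all gaitevents errors."""


class FormatError(GaitEventsError):
    """A file does not conform to the expected format."""


class EmptyInputError(GaitEventsError):
    """An input contains no usable samples or rows."""


class ValidationError(GaitEventsError):
    """An input violates a documented precondition or invariant."""


class DegenerateGeometryError(GaitEventsError):
    """Marker geometry does not define an orientation (coincident points)."""


class InsufficientDataError(GaitEventsError):
    """Too few samples or pairs for the requested computation."""


class ConfigError(GaitEventsError):
    """A configuration value is out of range or internally inconsistent."""
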