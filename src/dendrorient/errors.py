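"""Exception hierarchy for dendrorient."""


class DendrorientError(Exception):
    """Base class for all package errors."""


class SWCParseError(DendrorientError):
    """Malformed SWC morphology file (bad line, cycle, missing soma)."""


class MapValidationError(DendrorientError):
    """Map document violates its schema or invariants."""


class GeometryError(DendrorientError):
    """Degenerate geometry (coincident soma/reference point, equal rays)."""


class UndefinedMeanError(DendrorientError):
    """Circular mean direction is undefined (resultant length ~ 0)."""
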