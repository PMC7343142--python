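"""Exception hierarchy shared across the pipeline."""


class BeeRangesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BeeRangesError):
    """A file does not conform to the expected layout (missing column, bad header)."""


class RecordError(BeeRangesError):
    """A single record is invalid; the message names the offending row."""


class ValidationError(BeeRangesError):
    """Geometry or label validation failed (overlap, self-intersection, unknown class)."""


class ConfigError(BeeRangesError):
    """A configuration value violates its constraints."""


class InsufficientDataError(BeeRangesError):
    """Too few observations for the requested computation."""


class DegenerateHullError(BeeRangesError):
    """Point set is collinear (or worse): the convex hull has no area."""


class SamplingError(BeeRangesError):
    """Rejection sampling failed (pathologically thin polygon)."""


class StageWindowError(BeeRangesError):
    """A capture date falls outside the configured flowering-season window."""
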