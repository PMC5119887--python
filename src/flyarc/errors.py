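"""Exception types shared across the pipeline stages."""


class FlyArcError(Exception):
    """Base class for all flyarc errors."""


class ParameterError(FlyArcError, ValueError):
    """A parameter is non-finite, out of range, or inconsistent."""


class MissingFeature(FlyArcError):
    """Fewer than two foreground features found in a capillary ROI."""


class AmbiguousFeature(FlyArcError):
    """More than two foreground features remain after size filtering."""


class NoObject(FlyArcError):
    """No pixel exceeded the object threshold after reference subtraction."""


class DegenerateSeries(FlyArcError):
    """A series is too short or has no variance where variance is required."""


class SchemaError(FlyArcError, ValueError):
    """A CSV or config file violated its schema; message names the offending row."""
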