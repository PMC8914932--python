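"""Exception hierarchy for the sensorized-prosthetic-foot toolkit."""


class SpfError(Exception):
    """Base class for all toolkit errors."""


class ShapeError(SpfError, ValueError):
    """A signal or frame has the wrong length / channel count."""


class DomainError(SpfError, ValueError):
    """A value lies outside its physically meaningful domain."""


class ConfigurationError(SpfError, ValueError):
    """Inconsistent configuration (thresholds, rates, branch intervals)."""


class DegenerateLoadError(SpfError, ArithmeticError):
    """Foot reported as loaded but the CoP denominator is zero."""


class EventStructureError(SpfError, ValueError):
    """Gait events do not alternate heel-strike / toe-off as required."""
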