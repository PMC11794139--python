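"""Exception hierarchy shared across phasekit."""


class PhasekitError(Exception):
    """Base class for all phasekit errors."""


class ValidationError(PhasekitError, ValueError):
    """Input data violates a documented invariant (bad alphabet, shapes, signs)."""


class FormatError(PhasekitError, ValueError):
    """A file does not conform to the expected on-disk format."""


class SchemaError(FormatError):
    """A delimited table is missing a required column or has an uncoercible type."""


class ConfigurationError(PhasekitError, ValueError):
    """A parameter or configuration value is inconsistent (even window, bad map)."""


class DegenerateTraceError(PhasekitError, ValueError):
    """A trace carries no usable signal for the requested operation."""
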