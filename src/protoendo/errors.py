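"""Exception types shared across the package."""


class ProtoendoError(Exception):
    """Base class for all package errors."""


class InvalidShapeError(ProtoendoError, ValueError):
    """A membrane contour violates its invariants (too few markers,
    negative radii, self-intersection, non-positive volume)."""


class StepSizeError(ProtoendoError, RuntimeError):
    """The integrator could not find a stable step size."""


class InfeasibleStockError(ProtoendoError, ValueError):
    """A requested concentration change cannot be realized from the
    given stock (denominator of the mixing equation is non-positive)."""


class SchemaError(ProtoendoError, ValueError):
    """A tabular file does not match its expected column schema."""


class ConfigError(ProtoendoError, ValueError):
    """A configuration file failed validation."""
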