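"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model or generator parameter violates its constraints."""


class SchemaError(ValueError):
    """A plate CSV does not conform to the long-format schema."""


class RaggedGridError(SchemaError):
    """Wells in a plate file do not share a common uniform time grid."""


class NoGrowthError(RuntimeError):
    """The OD trace never reaches the requested threshold."""


class IdentifiabilityError(RuntimeError):
    """The lagged regressor matrix is rank deficient for a non-trivial output."""


class MappingError(RuntimeError):
    """A discrete pole sits where the bilinear map is singular (z = -1)."""
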