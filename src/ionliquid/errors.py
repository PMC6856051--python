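"""Exception types shared across the package."""


class IonLiquidError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(IonLiquidError, ValueError):
    """Invalid parameter or configuration value."""


class LiquidStateError(IonLiquidError, ValueError):
    """The liquid reached or was handed an invalid state (e.g. non-finite voltage)."""


class BoundsError(IonLiquidError, IndexError):
    """A coordinate falls outside the voltage grid."""


class CapacityError(IonLiquidError, ValueError):
    """A request exceeds what the grid can hold (e.g. more sources than bins)."""


class FormatError(IonLiquidError, ValueError):
    """A serialized artifact does not match the expected schema."""


class GenerationError(IonLiquidError, RuntimeError):
    """Random generation could not satisfy its constraints."""


class SearchError(IonLiquidError, RuntimeError):
    """A sampling search exhausted its budget without an acceptable result."""
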