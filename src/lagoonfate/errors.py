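"""Exception types shared across the model."""


class LagoonFateError(Exception):
    """Base class for all model errors."""


class InvalidInputError(LagoonFateError, ValueError):
    """An input violates a physical precondition (negative concentration, ...)."""


class DegenerateInputError(LagoonFateError, ValueError):
    """An input combination makes the requested quantity undefined (e.g. H' = 0)."""


class StabilityError(LagoonFateError, RuntimeError):
    """An explicit time step violates a stability bound or produced negatives."""


class ConservationError(LagoonFateError, RuntimeError):
    """The mass ledger closed with a residual above tolerance."""


class ConfigError(LagoonFateError, ValueError):
    """Geometry/configuration references an unknown box or is inconsistent."""


class UnitError(LagoonFateError, ValueError):
    """A declared unit in an input file does not match the expected unit."""


class ForcingParseError(LagoonFateError, ValueError):
    """A forcing or boundary table could not be parsed."""
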