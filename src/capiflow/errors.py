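"""Exception hierarchy for capiflow."""


class CapiflowError(Exception):
    """Base class for all capiflow errors."""


class InvalidGeometryError(CapiflowError, ValueError):
    """Capillary axes are non-positive, NaN, or mis-ordered."""


class ConfigurationError(CapiflowError, ValueError):
    """A required piece of configuration is missing or inconsistent."""


class DomainError(CapiflowError, ValueError):
    """An argument lies outside the physical domain of the model."""


class SingularStateError(CapiflowError, ValueError):
    """The flow state is singular (zero wetted length)."""


class InfeasibleObservationError(CapiflowError, ValueError):
    """An observation implies parameters outside their physical range."""


class InsufficientDataError(CapiflowError, ValueError):
    """Too few usable data points for the requested operation."""


class IntegrationError(CapiflowError, RuntimeError):
    """The trajectory integrator produced a non-physical solution."""


class RenderError(CapiflowError, ValueError):
    """A trajectory cannot be rendered into the configured image extent."""
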