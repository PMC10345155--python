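"""Exception types shared across the package."""


class GPX4KinError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GPX4KinError, ValueError):
    """An input lies outside the physically meaningful domain."""


class IntegrationError(GPX4KinError, RuntimeError):
    """The ODE solver failed to produce a trajectory."""


class IdentifiabilityError(GPX4KinError, ValueError):
    """The experimental design cannot constrain the requested parameters."""


class DataInconsistencyError(GPX4KinError, ValueError):
    """A trace is internally inconsistent (e.g. implies negative substrate)."""


class ConfigError(GPX4KinError, ValueError):
    """Invalid pipeline or generator configuration."""
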