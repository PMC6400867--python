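"""Exception hierarchy shared across the pipeline stages."""


class StresscompError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StresscompError):
    """A configuration object violates its invariants."""


class DataError(StresscompError):
    """An input record is malformed or outside the supported domain."""


class InitializationError(StresscompError):
    """The MCMC sampler could not find a finite starting state."""


class ArtifactMismatchError(StresscompError):
    """Artifacts produced under different configurations were combined."""
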