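"""Exception hierarchy shared across the package."""


class NetblocksError(Exception):
    """Base class for all package-specific errors."""


class EdgeListParseError(NetblocksError):
    """A malformed line was encountered while reading an edge list."""


class GraphDomainError(NetblocksError, ValueError):
    """An operation was applied to a graph outside its domain."""


class SamplingError(NetblocksError):
    """A sampler could not produce a sample (e.g. restart budget exhausted)."""


class EstimationError(NetblocksError):
    """A diffusion estimate could not be formed (e.g. all runs censored)."""


class FitError(NetblocksError):
    """A curve fit received degenerate input."""


class GenerationError(NetblocksError):
    """The synthetic generator missed its target statistics."""


class EvaluationError(NetblocksError):
    """The regression evaluation received invalid input."""


class ConfigError(NetblocksError):
    """An invalid configuration value was supplied."""
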