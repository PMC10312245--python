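"""Exception types shared across the pipeline."""


class CoopnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CoopnetError, ValueError):
    """A configuration object violates its invariants."""


class ConsistencyError(CoopnetError, ValueError):
    """Input tables disagree with each other (unknown ids, mismatched rosters)."""


class UndefinedMetricError(CoopnetError, ValueError):
    """A network metric is undefined for the given graph (too few nodes, no edges)."""


class DegenerateNullError(CoopnetError, ValueError):
    """The random-graph null distribution has zero spread."""


class EstimationError(CoopnetError, ValueError):
    """GMM estimation cannot proceed (no usable observations, singular weighting)."""


class NonConvergenceError(CoopnetError, RuntimeError):
    """An iterative computation failed to converge within its iteration budget."""
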