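"""Exception hierarchy for nodesig.

Every operational failure raises a subclass of :class:`NodesigError` so
callers can distinguish pipeline faults from programming errors.
"""


class NodesigError(Exception):
    """Base class for all nodesig errors."""


class InvalidInputError(NodesigError):
    """Input fails a precondition (shape, type, or configuration)."""


class EmptyResultError(NodesigError):
    """An operation produced nothing (e.g. a filter removed every sample)."""


class MissingFeatureError(NodesigError):
    """A required gene or probe is absent from the matrix."""


class CorruptFixtureError(NodesigError):
    """A bundled fixture violates its own invariants."""


class UndefinedStatisticError(NodesigError):
    """A statistic has no defined value (constant vector, no comparable pairs)."""


class DegenerateSplitError(NodesigError):
    """A grouping left one group empty (e.g. median split with massive ties)."""


class ConvergenceError(NodesigError):
    """An iterative fit failed to converge; carries diagnostics in args."""


class EmptySignatureError(NodesigError):
    """Feature selection retained no genes."""


class EmptyOverlapError(NodesigError):
    """A gene set shares no member with the ranked list."""


class DegenerateSetError(NodesigError):
    """A gene set covers the entire ranked list, leaving no misses."""
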