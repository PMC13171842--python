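"""Exception hierarchy shared across the package."""


class NutrigraphError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NutrigraphError):
    """Input table violates the expected schema (duplicates, bad columns)."""


class LinkageError(NutrigraphError):
    """A reference (e.g. disease -> nutrient) cannot be resolved in the graph."""


class UnitError(NutrigraphError):
    """Unknown or incompatible measurement unit."""


class ImputationError(NutrigraphError):
    """Missing-value imputation is impossible (nutrient observed nowhere)."""


class ResolutionError(NutrigraphError):
    """No demographic RDA band covers the requested profile."""


class NotFoundError(NutrigraphError):
    """A named node does not exist in the graph."""


class NoMatchError(NutrigraphError):
    """Semantic matching found no candidate above the similarity threshold."""

    def __init__(self, message, nearest=()):
        super().__init__(message)
        #: closest candidates as (name, similarity) pairs, best first
        self.nearest = tuple(nearest)


class NoCandidatesError(NutrigraphError):
    """No food in the graph contains any of the required nutrients."""


class ValidationError(NutrigraphError):
    """Invalid argument to a metric or formatting operation."""
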