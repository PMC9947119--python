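"""Exception hierarchy shared across the package.

Every error raised by rhizomics derives from :class:`RhizomicsError` so
callers can catch package failures with a single except clause.
"""


class RhizomicsError(Exception):
    """Base class for all rhizomics errors."""


class InvalidDesignError(RhizomicsError):
    """A study design or generator parameterization is internally inconsistent."""


class SchemaError(RhizomicsError):
    """Input tables disagree on sample or taxon identifiers."""


class InvalidArgumentError(RhizomicsError):
    """An argument is outside its documented domain."""


class DepthError(RhizomicsError):
    """Requested rarefaction depth exceeds the library size of some samples."""


class UndefinedDiversityError(RhizomicsError):
    """Diversity index requested for an all-zero abundance vector."""


class UndefinedDistanceError(RhizomicsError):
    """Dissimilarity requested for an all-zero abundance vector."""


class UnderdeterminedDesignError(RhizomicsError):
    """A grouping factor has a level with too few samples for the test."""


class MissingTipError(RhizomicsError):
    """Community taxa are absent from the phylogeny."""

    def __init__(self, taxa):
        self.taxa = sorted(taxa)
        super().__init__(f"taxa missing from tree: {self.taxa}")


class UndefinedZScoreError(RhizomicsError):
    """Null distribution has zero spread; the z-score is undefined."""


class InvalidPoolError(RhizomicsError):
    """Species-pool input for a null model is empty or inconsistent."""


class EmptyNetworkError(RhizomicsError):
    """No taxa survive the prevalence/abundance filter."""


class ImpossibleGraphError(RhizomicsError):
    """Requested random graph has more edges than the complete graph allows."""


class InsufficientClassError(RhizomicsError):
    """A class has too few samples for a stratified split or CV."""
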