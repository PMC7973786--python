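"""Exception hierarchy for atlas construction and analysis."""


class FlexAtlasError(Exception):
    """Base class for all package-specific errors."""


class OntologyIntegrityError(FlexAtlasError):
    """The ontology tree violates a structural invariant (duplicate ids,
    multiple roots, orphan nodes, broken parent/child links)."""


class OntologyLookupError(FlexAtlasError, KeyError):
    """A node id or acronym was not found in the ontology."""


class ConsistencyError(FlexAtlasError):
    """Ontology and annotation volume disagree (unknown labels, unmapped ids)."""


class ConfigurationError(FlexAtlasError):
    """A configured branch acronym or axis declaration is missing/invalid."""


class CombineSpecError(FlexAtlasError):
    """A combine target is invalid (leaf node, nested targets)."""


class AllocationError(FlexAtlasError):
    """A freshly allocated node id collides with an existing one."""


class FitError(FlexAtlasError):
    """Histogram mixture fit failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SampleSizeError(FlexAtlasError):
    """Too few values to fit a threshold model."""


class DegenerateSplitError(FlexAtlasError):
    """A division threshold puts every voxel on one side; node left untouched."""


class CoverageError(FlexAtlasError):
    """Time series are missing for some descendant leaves of an inner node."""


class PairingError(FlexAtlasError):
    """Conditions do not share run ids for a paired/repeated-measures test."""


class InsufficientDataError(FlexAtlasError):
    """Fewer runs than the statistical procedure requires."""


class CapacityError(FlexAtlasError):
    """The synthetic grid is too small to host the requested nodes."""
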