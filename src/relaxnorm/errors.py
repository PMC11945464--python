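"""Exception hierarchy shared across the package."""


class RelaxnormError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RelaxnormError):
    """A file could not be read as the expected volume format."""


class GridMismatchError(RelaxnormError):
    """Volumes that must share one sampling grid do not."""


class CohortTableError(RelaxnormError):
    """A cohort metadata table is malformed or fails validation."""


class InvalidSpecError(RelaxnormError):
    """A phantom specification describes degenerate geometry or parameters."""


class ConfigurationError(RelaxnormError):
    """An analysis setting is out of its documented range."""


class DegenerateMaskError(RelaxnormError):
    """An analysis mask ended up empty."""


class DesignError(RelaxnormError):
    """The regression design matrix is rank-deficient (too few distinct ages)."""


class FitFailureError(RelaxnormError):
    """A model fit produced no valid voxels."""
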