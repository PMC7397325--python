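"""Exception hierarchy shared across the package."""


class ProstasigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ProstasigError):
    """A simulation or analysis configuration field is invalid."""


class FormatError(ProstasigError):
    """A file violates the expected on-disk format."""


class MergeError(ProstasigError):
    """Cohorts cannot be merged (e.g. empty gene intersection)."""


class DegenerateSampleError(ProstasigError):
    """A sample has zero expression variance, so z-scoring is undefined."""


class MissingGeneError(ProstasigError):
    """None of a gene set's members are present in the matrix."""


class DegenerateInputError(ProstasigError):
    """An input is empty or otherwise carries no usable information."""


class UnassignableError(ProstasigError):
    """A sample cannot be assigned to any factor/subgroup."""


class TrainingError(ProstasigError):
    """Classifier training preconditions are not met."""


class SurvivalError(ProstasigError):
    """A survival analysis cannot be carried out on the given data."""
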