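"""Exception hierarchy shared across the pipeline."""


class PhenocastError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhenocastError):
    """Invalid configuration (unknown labels, inconsistent year splits, ...)."""


class SchemaError(PhenocastError):
    """A table is missing required columns or violates basic invariants."""


class DataQualityError(PhenocastError):
    """Input data are present but unusable (e.g. too many missing hours)."""


class GenerationError(PhenocastError):
    """The synthetic generator was asked for a physically impossible vine."""


class DegenerateFitError(PhenocastError):
    """A curve fit is undefined for this vine (all-zero / saturated counts)."""


class ExtrapolationError(PhenocastError):
    """A fitted curve never reaches the requested level in the search range."""


class DomainError(PhenocastError):
    """An argument is outside the mathematical domain of a formula."""
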