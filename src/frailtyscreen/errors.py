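"""Exception hierarchy for the frailty screening pipeline."""


class FrailtyScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FrailtyScreenError):
    """Invalid generator / scoring / run configuration."""


class SchemaError(FrailtyScreenError):
    """A cohort or result table violates its declared schema."""


class CodingError(FrailtyScreenError):
    """An unknown category code in a questionnaire-derived field."""


class StratificationError(FrailtyScreenError):
    """A cutoff stratum is empty or a stratification key is missing."""


class PipelineError(FrailtyScreenError):
    """A pipeline stage could not complete; message names the stage."""
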