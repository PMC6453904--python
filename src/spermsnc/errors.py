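"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """A file could not be parsed (FASTA/FASTQ/identifier grammar)."""


class ValidationError(PipelineError):
    """An object violates a documented invariant."""


class SchemaError(PipelineError):
    """A tabular file is missing a required column."""


class ConfigError(PipelineError):
    """A pipeline configuration is invalid or contains unknown keys."""
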