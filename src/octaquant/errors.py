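"""Exception hierarchy shared across the package."""


class OCTAQuantError(Exception):
    """Base class for all package errors."""


class DomainError(OCTAQuantError, ValueError):
    """Input outside the physically/mathematically valid domain."""


class FormatError(OCTAQuantError, ValueError):
    """A file or record does not conform to the expected format."""


class MetadataError(OCTAQuantError, ValueError):
    """Required per-eye metadata is missing or invalid."""


class ValidationError(OCTAQuantError, ValueError):
    """Structured input fails an internal consistency check."""


class ConfigError(OCTAQuantError, ValueError):
    """Invalid configuration or parameter combination."""


class DegenerateInputError(OCTAQuantError, ValueError):
    """Input is technically valid but leaves the operation undefined
    (e.g. an empty measurement region)."""


class SingularDesignError(OCTAQuantError, ValueError):
    """Regression design matrix is rank-deficient."""


class GenerationError(OCTAQuantError, RuntimeError):
    """A synthetic-data target could not be met within bounded retries."""
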