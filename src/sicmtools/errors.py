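"""Exception hierarchy shared across the package."""


class SICMError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SICMError):
    """A file does not conform to its declared on-disk format."""


class DataError(SICMError):
    """File parsed correctly but holds invalid values (NaN/inf cells, ...)."""


class ConfigurationError(SICMError):
    """Inconsistent or missing configuration/metadata."""


class PipelineError(SICMError):
    """A pipeline stage failed; the message is tagged with the stage name."""
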