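"""Exception types shared across the package."""


class AkwMrpkError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AkwMrpkError):
    """Input file violates the expected layout (e.g. no header row)."""


class ParseError(AkwMrpkError):
    """A cell could not be converted to a number; message names row/column."""


class LabelError(AkwMrpkError):
    """Label column contains values outside {0, 1}."""


class ConfigError(AkwMrpkError):
    """A configuration object is internally inconsistent."""


class PipelineError(AkwMrpkError):
    """A pipeline stage failed; message is prefixed with the stage name."""
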