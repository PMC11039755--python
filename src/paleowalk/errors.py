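"""Exception types shared across the package."""


class PaleowalkError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PaleowalkError, ValueError):
    """An input violates a documented precondition."""


class ConfigurationError(PaleowalkError, ValueError):
    """A parameter set is internally inconsistent (e.g. unstable time step)."""


class FormatError(PaleowalkError, ValueError):
    """A file could not be parsed or failed validation; message names the file/field."""


class PipelineError(PaleowalkError, RuntimeError):
    """A pipeline stage failed or a resume precondition is missing."""
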