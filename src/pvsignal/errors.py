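"""Exception types shared across the pipeline."""


class PvSignalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PvSignalError, ValueError):
    """Invalid simulation or analysis configuration."""


class ParseError(PvSignalError, ValueError):
    """Malformed input file; message names the file and, where known, the line."""


class ValidationError(PvSignalError, ValueError):
    """Inputs violate a documented precondition."""
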