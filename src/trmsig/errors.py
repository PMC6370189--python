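"""Exception hierarchy shared across the pipeline stages."""


class TrmsigError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(TrmsigError):
    """Invalid parameters, thresholds or input combinations."""

    exit_code = 2


class ParseError(TrmsigError):
    """Malformed input file; the message names the file and line."""

    exit_code = 3


class StageError(TrmsigError):
    """A pipeline stage failed on otherwise well-formed input."""

    exit_code = 4
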