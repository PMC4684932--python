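"""Exception hierarchy with stable CLI exit codes."""


class NestpowerError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(NestpowerError):
    """A call that cannot be honoured for the given data/design (wrong design,
    missing condition, unknown method name, ...)."""

    exit_code = 2


class InvalidParameterError(NestpowerError):
    """A parameter value outside its mathematical domain (negative variance,
    ICC >= 1, non-PSD random-effects covariance, ...)."""

    exit_code = 3


class DataFormatError(NestpowerError):
    """Malformed dataset file or config file."""

    exit_code = 3


class ConvergenceThresholdError(NestpowerError):
    """Too large a fraction of Monte-Carlo replicates failed to converge."""

    exit_code = 4
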