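"""Exception hierarchy shared across the pipeline stages."""


class GblicaError(Exception):
    """Base class for all package errors."""


class ParameterError(GblicaError, ValueError):
    """An argument value is invalid or inconsistent."""


class DimensionError(ParameterError):
    """Matrix/array dimensions are inconsistent."""


class ParseError(GblicaError, ValueError):
    """An input file could not be parsed; the message names the offender."""


class RankDeficientError(ParameterError):
    """A regression design matrix is rank deficient."""


class ConvergenceError(GblicaError, RuntimeError):
    """A numerical update produced non-finite values."""


class PipelineError(GblicaError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
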