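"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: configuration/parameter problems map to
exit code 2, data/format/analysis problems to exit code 3.
"""


class MethMirNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MethMirNetError):
    """A configuration object violates one of its documented bounds."""


class ParameterError(MethMirNetError):
    """An operation argument is outside its documented domain."""


class FormatError(MethMirNetError):
    """An external file violates the expected dialect or an invariant."""


class PoolingError(MethMirNetError):
    """Dataset pooling is impossible (e.g. empty feature intersection)."""


class AlignmentError(MethMirNetError):
    """Two per-patient/per-sample objects do not share the same index."""


class AnalysisError(MethMirNetError):
    """An analysis stage cannot proceed on the given data."""


class UndefinedResultError(AnalysisError):
    """The requested statistic is undefined on this input (empty overlap,
    zero variance, ...)."""
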