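"""Exception hierarchy.

Every error raised by this package derives from :class:`VococoordError`
so callers can catch the whole family. Errors are split between
specification problems (bad parameters, malformed configs) and data
problems (degenerate inputs encountered at run time); the pipeline
treats the former as fatal and the latter as per-recording exclusions.
"""


class VococoordError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(VococoordError, ValueError):
    """A generative or combination spec violates its invariants."""


class InvalidInputError(VococoordError, ValueError):
    """An input waveform or trajectory is unusable (empty, non-finite...)."""


class InvalidLabelsError(VococoordError, ValueError):
    """The label table is missing required columns or malformed."""


class MissingChannelError(VococoordError, KeyError):
    """A combination references a channel absent from the recording."""


class InsufficientOverlapError(VococoordError):
    """Too few jointly valid sample pairs to estimate a correlation."""


class UndefinedCorrelationError(VococoordError):
    """A paired slice has zero variance; Pearson r is undefined."""


class InvalidMatrixError(VococoordError, ValueError):
    """Correlation matrix contains NaN or is otherwise unusable."""


class InsufficientGroupError(VococoordError):
    """An effect-size group has fewer than two observations."""


class UndefinedEffectError(VococoordError):
    """Pooled variance is zero; Cohen's d is undefined."""


class InsufficientPatternError(VococoordError):
    """Too few non-missing ranks to classify an effect-size pattern."""


class UndefinedSpectrumError(VococoordError):
    """Spectrum flatness requested for an all-zero eigenvalue spectrum."""


class ConfigurationError(VococoordError, ValueError):
    """Analysis configuration is unusable (e.g. empty post-filter corpus)."""
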