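"""Exception hierarchy for the screen pipeline.

Every stage raises a dedicated subclass of :class:`ScreenError` so the CLI
can report which stage failed and which record was responsible.
"""


class ScreenError(Exception):
    """Base class for all pipeline errors."""


class ParseError(ScreenError):
    """A tabular input file could not be parsed or violated an invariant."""


class AnnotationError(ScreenError):
    """A compound-annotation table violated an invariant."""


class NormalizationError(ScreenError):
    """Relative-viability normalization could not be performed (e.g. a
    plate is missing vehicle wells)."""


class ScoringError(ScreenError):
    """A dose-response profile could not be scored (incomplete grid,
    non-finite viability, zero replicates)."""


class StatisticsError(ScreenError):
    """Too few observations for the requested statistic."""


class QCError(ScreenError):
    """A control-compound series required for QC is missing."""


class QCFailure(ScreenError):
    """Raised in strict mode when control-compound QC gates fail."""


class GroupingError(ScreenError):
    """A hit compound lacks an annotation record."""


class GenerationError(ScreenError):
    """The synthetic generator was misconfigured."""
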