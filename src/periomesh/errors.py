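"""Exception hierarchy.

Every anticipated per-tooth failure derives from :class:`PeriomeshError` so the
pipeline can isolate a failing tooth (recording an ``unmeasurable`` status)
without aborting the cohort run.
"""


class PeriomeshError(Exception):
    """Base class for all errors raised by periomesh."""


class StlFormatError(PeriomeshError):
    """Malformed STL input (names the byte offset or line where possible)."""


class EmptySelectionError(PeriomeshError):
    """A crop produced no faces."""


class AlignmentError(PeriomeshError):
    """Rigid alignment could not be computed (degenerate or too few points)."""


class AmbiguousAxisError(PeriomeshError):
    """Tooth-axis estimation failed (degenerate crown covariance, no hint)."""


class EmptySectionError(PeriomeshError):
    """The cutting plane does not intersect the mesh."""


class MissingGingivaError(PeriomeshError):
    """A section contains no gingiva-labelled points."""


class NoIntersectionError(PeriomeshError):
    """The horizontal line L does not cross the section polyline."""


class ConfigError(PeriomeshError):
    """Invalid pipeline or simulation configuration."""
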