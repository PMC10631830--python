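"""Exception hierarchy shared across the package.

All domain errors derive from :class:`PVLoopError` so callers can catch a
single base class; each subclass also inherits from the closest built-in
(``ValueError`` or ``RuntimeError``) to stay idiomatic.
"""


class PVLoopError(Exception):
    """Base class for all pvloop-specific errors."""


class DegenerateCurveError(PVLoopError, ValueError):
    """Volume curve has no stroke (EDV == ESV) or is otherwise unusable."""


class DegenerateLoopError(PVLoopError, ValueError):
    """PV loop has fewer than three distinct vertices."""


class DegenerateGeometryError(PVLoopError, ValueError):
    """Loop geometry breaks a slope definition (e.g. EDV <= Emax volume)."""


class PressureOrderingError(PVLoopError, ValueError):
    """Pressure inputs violate required ordering (e.g. LVPsys <= EDP)."""


class InvalidBPError(PVLoopError, ValueError):
    """Brachial pressure pair violates SBP > DBP > 0."""


class SegmentationError(PVLoopError, RuntimeError):
    """No beats could be detected in a catheter recording."""


class FrequentEctopyError(PVLoopError, RuntimeError):
    """Ectopic fraction exceeds the exclusion threshold; recording rejected."""


class ChannelError(PVLoopError, ValueError):
    """Required recording channel missing or unusable."""


class ConvergenceError(PVLoopError, RuntimeError):
    """Iterative solver failed to converge."""


class DegenerateRegressorError(PVLoopError, ValueError):
    """Regression requested on a constant predictor."""


class UndefinedICCError(PVLoopError, ValueError):
    """ICC undefined because the data carry no variance."""


class ConfigError(PVLoopError, ValueError):
    """Configuration file malformed or field out of range."""
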