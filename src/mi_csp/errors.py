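"""Exception hierarchy.

All package-specific failures derive from :class:`MiCspError` so callers can
catch one base class at pipeline level while tests assert on the precise
subclass.
"""


class MiCspError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(MiCspError):
    """An invalid parameter or configuration value; names the violated rule."""


class FormatError(MiCspError):
    """A file could not be parsed; names the missing/malformed variable."""


class EstimationError(MiCspError):
    """A model fit failed (non-convergence, rank deficiency, single class)."""


class EpochingError(MiCspError):
    """A trial window falls outside the recorded signal."""


class DegenerateInputError(MiCspError):
    """Input data carries no usable signal (all-zero trial, zero variance)."""
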