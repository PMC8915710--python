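"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`PPGVolError`, so callers can catch one type at the CLI boundary.
"""


class PPGVolError(Exception):
    """Base class for all errors raised by ppgvol."""


class ConfigError(PPGVolError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class FormatError(PPGVolError, ValueError):
    """A file on disk does not conform to the expected text dialect."""


class LinkageError(PPGVolError, ValueError):
    """A cohort references a trial file that cannot be resolved."""


class DetectionError(PPGVolError, RuntimeError):
    """Beat detection failed (too short, flat, or unpulsatile signal)."""


class WidthError(PPGVolError, RuntimeError):
    """The half-height level of a beat is never crossed; beat is dropped."""


class WindowingError(PPGVolError, RuntimeError):
    """An analysis window contains too few beats or lies outside the trial."""


class ModelingError(PPGVolError, RuntimeError):
    """A model fit is infeasible (rank deficiency, bad folds, one class)."""


class UsageError(PPGVolError, ValueError):
    """An API was called with arguments outside its contract."""
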