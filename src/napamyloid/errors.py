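"""Exception hierarchy for the napamyloid pipeline."""


class NapamyloidError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(NapamyloidError, ValueError):
    """A configuration object violates its invariants."""


class DegenerateWaveformError(NapamyloidError, ValueError):
    """A trace is flat or otherwise unmarkable."""


class UndefinedRatioError(NapamyloidError, ValueError):
    """A ratio feature has a non-positive reference amplitude."""


class UnregistrableRecordError(NapamyloidError, ValueError):
    """A waveform cannot be registered (e.g. zero peak-to-peak amplitude)."""


class FitFailureError(NapamyloidError, RuntimeError):
    """The registration optimizer produced a non-finite or invalid result."""


class InsufficientDataError(NapamyloidError, ValueError):
    """Not enough observations/groups/points for a statistical procedure."""


class UnbalancedPanelError(NapamyloidError, ValueError):
    """A repeated-measures panel is incomplete; no silent imputation is done."""
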