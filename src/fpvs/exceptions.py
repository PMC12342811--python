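"""Exception hierarchy for the fpvs package."""


class FPVSError(Exception):
    """Base class for all fpvs errors."""


class InvalidParameterError(FPVSError, ValueError):
    """A parameter violates its documented domain (e.g. negative rate)."""


class MisalignedFrequencyError(FPVSError, ValueError):
    """A target frequency does not coincide with a spectral bin."""


class DegenerateSpectrumError(FPVSError, ArithmeticError):
    """Neighbouring-bin spread is zero; the Z-score is undefined."""


class DegenerateBaselineError(FPVSError, ArithmeticError):
    """Baseline standard deviation is zero; latency thresholds are undefined."""


class EmptyResultError(FPVSError, RuntimeError):
    """An operation retained no data (e.g. every epoch fell outside the sequence)."""


class NoReferencePhaseError(FPVSError, RuntimeError):
    """No voxel passed the threshold used to estimate the reference phase."""
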