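"""Exception hierarchy for the nnufti package.

All package errors derive from :class:`NnuftiError` so callers can catch
one base class; individual subclasses also derive from the closest
builtin (ValueError / IOError) so generic handling keeps working.
"""


class NnuftiError(Exception):
    """Base class for all nnufti errors."""


class VolumeFormatError(NnuftiError, IOError):
    """A volume/mask file could not be read or has the wrong dimensionality."""


class GeometryError(NnuftiError, ValueError):
    """Volume and mask grids do not match."""


class MaskValidationError(NnuftiError, ValueError):
    """A liver VOI mask is empty or otherwise invalid."""


class ParameterError(NnuftiError, ValueError):
    """An analysis parameter is outside its allowed set (e.g. connectivity)."""


class DomainError(NnuftiError, ValueError):
    """An input value violates a mathematical precondition (e.g. C_thr > C_max)."""


class CurveParseError(NnuftiError, ValueError):
    """A curve or cohort CSV is malformed."""


class NoCrossingError(NnuftiError, ValueError):
    """The nNUFTI curve never crosses the requested nNUF level on that side."""

    def __init__(self, side: str, level: float, min_nnuf: float):
        self.side = side
        self.level = level
        self.min_nnuf = min_nnuf
        super().__init__(
            f"no nNUF={level:g} crossing on the {side} branch "
            f"(minimum nNUF reached on that side: {min_nnuf:g})"
        )


class DegenerateDataError(NnuftiError, ValueError):
    """Groups have zero pooled variance; a t statistic is undefined."""


class CalibrationError(NnuftiError, ValueError):
    """No nNUF level admits a defined t score on either side."""


class FitError(NnuftiError, ValueError):
    """The concentration-model design matrix is rank deficient."""


class UndefinedPPVError(NnuftiError, ValueError):
    """No patient (positive or negative) reaches the threshold: PPV undefined."""


class PhantomSpecError(NnuftiError, ValueError):
    """A phantom specification is inconsistent (e.g. lesion outside the VOI)."""


class ExtrapolationWarning(UserWarning):
    """Mean concentration far outside the fitted range; nThI is extrapolated."""
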