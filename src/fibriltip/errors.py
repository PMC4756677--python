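"""Exception and warning types shared across the package."""


class FibriltipError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FibriltipError, ValueError):
    """A rate constant, condition, or argument is out of its allowed range."""


class NotAnalyticError(FibriltipError):
    """Closed-form theory was requested for a rate set outside its assumptions.

    The closed forms require s_bc = 0 and k_d_bb = 0; use the kmc module for
    anything else.
    """


class NonStationaryError(FibriltipError):
    """The tip cap has no stationary distribution (regime 2)."""


class TruncationError(FibriltipError):
    """The truncated master-equation chain is too small for the requested tail
    tolerance."""

    def __init__(self, msg, suggested_kmax=None):
        super().__init__(msg)
        self.suggested_kmax = suggested_kmax


class NoGrowthError(FibriltipError):
    """The filament does not grow at zero load; a stall force is undefined."""


class InsufficientDataError(FibriltipError):
    """Too few points/dwells/runs for the requested estimator."""


class UnknownUnitError(FibriltipError, ValueError):
    """Unit name not recognised by unit_convert."""


class ConfigError(FibriltipError, ValueError):
    """Malformed configuration file; the message names the offending key."""


class NoSaturationWarning(UserWarning):
    """A concentration-velocity curve is still rising at its top concentration;
    the reported switching rate is only a lower bound."""
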