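"""Parameter and state records of the two-state filament model.

The model describes a linear filament of protein monomers in one of two
conformations: an unstructured, coil-like state C and a beta-strand state B.
The filament is a contiguous beta-core (the B block) terminated by a cap of
k C monomers at the growing tip.  Six rate constants govern the dynamics:

======== ======================================================== ==========
field    event                                                    units
======== ======================================================== ==========
k_p_cc   C monomer binds a C monomer at the tip                   /uM /hr
k_d_cc   terminal C unbinds from a C monomer                      /hr
k_p_bc   C monomer binds the exposed B end (empty cap)            /uM /hr
k_d_bc   the single cap C unbinds from the B end                  /hr
s_cb     on-filament conformational switch C -> B (leftmost C)    /hr
s_bc     backward switch B -> C (rightmost B)                     /hr
k_d_bb   terminal B unbinds from a B monomer                      /hr
======== ======================================================== ==========

Internally time is measured in hours, length in monomers and concentration in
micromolar; polymerization propensities are ``k_p * conc``.  B-B contacts are
taken as effectively irreversible (``k_d_bb = 0``) and backward switching as
negligible (``s_bc = 0``) throughout the analytic theory; both fields exist so
the stochastic simulator can relax the assumptions for exploratory runs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import InvalidParameterError, NotAnalyticError, UnknownUnitError

__all__ = [
    "RateSet",
    "Conditions",
    "FilamentState",
    "rescale_rates",
    "unit_convert",
    "DEFAULT_RISE_NM",
]

#: Axial rise per monomer in a cross-beta stack, nm (2 monomers per nm).
DEFAULT_RISE_NM = 0.5


@dataclass(frozen=True)
class RateSet:
    """The six kinetic constants of the two-state model (plus ``k_d_bb``)."""

    k_p_cc: float
    k_d_cc: float
    k_p_bc: float
    k_d_bc: float
    s_cb: float
    s_bc: float = 0.0
    k_d_bb: float = 0.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(
                    f"rate constant {f.name} must be finite and >= 0, got {v!r}"
                )

    def require_analytic(self) -> None:
        """Raise unless this rate set satisfies the closed-form assumptions.

        The steady-state cap distribution and every velocity formula assume
        irreversible switching (``s_bc = 0``) and an inert beta core
        (``k_d_bb = 0``).
        """
        if self.s_bc != 0.0 or self.k_d_bb != 0.0:
            raise NotAnalyticError(
                "closed-form theory requires s_bc = 0 and k_d_bb = 0 "
                f"(got s_bc={self.s_bc}, k_d_bb={self.k_d_bb}); "
                "use fibriltip.kmc for reversible-switching dynamics"
            )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        return cls(**d)

    def replace(self, **kw) -> "RateSet":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Conditions:
    """External conditions: free monomer concentration and mechanical load.

    Parameters
    ----------
    conc : float
        Free monomer concentration, uM.
    force : float
        Opposing load on the growing tip, pN.
    alpha : float
        Load-distribution factor in [0, 1]: the fraction of the mechanical
        penalty ``F*d`` assigned to the polymerization step, the remainder
        amplifying depolymerization.
    rise : float
        Axial rise per monomer, nm (default 0.5, i.e. 2 monomers/nm).
    kBT : float
        Thermal energy, pN nm (default 4.1, room temperature).
    """

    conc: float
    force: float = 0.0
    alpha: float = 1.0
    rise: float = DEFAULT_RISE_NM
    kBT: float = 4.1

    def __post_init__(self):
        if not (math.isfinite(self.conc) and self.conc >= 0):
            raise InvalidParameterError(f"conc must be >= 0, got {self.conc!r}")
        if not (math.isfinite(self.force) and self.force >= 0):
            raise InvalidParameterError(f"force must be >= 0, got {self.force!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError(f"alpha must be in [0, 1], got {self.alpha!r}")
        if not self.rise > 0:
            raise InvalidParameterError(f"rise must be > 0, got {self.rise!r}")
        if not self.kBT > 0:
            raise InvalidParameterError(f"kBT must be > 0, got {self.kBT!r}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Conditions":
        return cls(**d)

    def replace(self, **kw) -> "Conditions":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class FilamentState:
    """Instantaneous single-filament state: beta-core size and cap size."""

    n_beta: int
    cap_k: int

    def __post_init__(self):
        if self.n_beta < 0 or self.cap_k < 0:
            raise InvalidParameterError(
                f"n_beta and cap_k must be >= 0, got ({self.n_beta}, {self.cap_k})"
            )

    @property
    def length(self) -> int:
        return self.n_beta + self.cap_k


def rescale_rates(rates: RateSet, cond: Conditions) -> RateSet:
    """Rescale the rate constants for growth against a constant opposing load.

    A load F on the tip raises the free-energy cost of adding one monomer by
    ``F*d`` (d = axial rise).  The penalty is split Boltzmann-fashion by the
    load-distribution factor alpha: both polymerization constants are
    attenuated by ``exp(-alpha*F*d/kBT)`` and both depolymerization rates
    amplified by ``exp((1-alpha)*F*d/kBT)``.  The on-filament switching rates
    are untouched: switching moves no mass against the load.

    The product of the two factors is ``exp(-F*d/kBT)`` for any alpha, so the
    equilibrium-constant shift is alpha-independent.
    """
    if cond.force < 0:
        raise InvalidParameterError("force must be >= 0")
    if cond.force == 0:
        return rates
    f = cond.force * cond.rise / cond.kBT
    on = math.exp(-cond.alpha * f)
    off = math.exp((1.0 - cond.alpha) * f)
    return rates.replace(
        k_p_cc=rates.k_p_cc * on,
        k_p_bc=rates.k_p_bc * on,
        k_d_cc=rates.k_d_cc * off,
        k_d_bc=rates.k_d_bc * off,
    )


# length unit -> monomers per unit (at rise = DEFAULT_RISE_NM; rescaled below)
_LENGTH_UNITS = ("monomers", "nm", "um")
_TIME_UNITS = {"hr": 1.0, "day": 24.0, "min": 1.0 / 60.0}


def _monomers_per(unit: str, rise: float) -> float:
    if unit == "monomers":
        return 1.0
    if unit == "nm":
        return 1.0 / rise
    if unit == "um":
        return 1000.0 / rise
    raise UnknownUnitError(
        f"unknown length unit {unit!r}; supported: {', '.join(_LENGTH_UNITS)}"
    )


def _parse_unit(unit: str):
    u = unit.strip().replace("μ", "u").replace("µ", "u")
    if "/" in u:
        num, _, den = u.partition("/")
        num, den = num.strip(), den.strip()
        if den not in _TIME_UNITS:
            raise UnknownUnitError(
                f"unknown time unit {den!r}; supported: {', '.join(_TIME_UNITS)}"
            )
        return num, den
    return u, None


def unit_convert(
    value: float, from_unit: str, to_unit: str, rise: float = DEFAULT_RISE_NM
) -> float:
    """Convert a length or velocity between the package's unit systems.

    Supported lengths: ``monomers``, ``nm``, ``um`` (``μm`` accepted);
    supported velocities: any ``<length>/<hr|day|min>``.  Conversion is exact
    and linear via the axial rise (default 0.5 nm/monomer, i.e. the
    2 monomers/nm of a cross-beta stack); round trips are identities.
    """
    f_len, f_time = _parse_unit(from_unit)
    t_len, t_time = _parse_unit(to_unit)
    if (f_time is None) != (t_time is None):
        raise UnknownUnitError(
            f"cannot convert between a length ({from_unit!r} or {to_unit!r}) "
            "and a velocity"
        )
    out = value * _monomers_per(f_len, rise) / _monomers_per(t_len, rise)
    if f_time is not None:
        # value per from-time -> value per hour -> value per to-time
        out = out / _TIME_UNITS[f_time] * _TIME_UNITS[t_time]
    return out
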