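"""Closed-form steady state of the tip-cap master equation and its corollaries.

With irreversible switching (s_bc = 0) and an inert beta core (k_d_bb = 0)
the cap size k is a birth-death chain:

* birth:  ``k_p_bc*c`` out of k = 0, ``k_p_cc*c`` for k >= 1;
* death:  ``k_d_bc + s_cb`` out of k = 1, ``k_d_cc + s_cb`` for k >= 2
  (a switch converts the leftmost cap C into B, shrinking the cap without
  shortening the filament).

Two dimensionless groups control everything::

    r(c) = k_p_cc * c / (k_d_cc + s_cb)      geometric cap-tail ratio
    a(c) = k_p_bc * c / (k_d_bc + s_cb)      empty-cap escape ratio

For r < 1 (regime 1) the chain is positive recurrent with

    P_0 = (1 - r) / (1 - r + a),     P_k = P_0 * a * r**(k-1)   (k >= 1)

and q = 1 - P_0 = a / (1 - r + a) is the probability of finding at least one
C at the tip.  The stationary filament velocity is the net polymerization
flux, which collapses to ``v_f = s_cb * q``: every permanent length gain is a
monomer locked in by a switch.  For r >= 1 (regime 2) the cap grows without
bound, the length velocity is the plain C-on-C flux ``k_p_cc*c - k_d_cc``,
and the beta front advances at exactly ``s_cb``.  The two regimes meet at the
characteristic concentration ``[C]** = (k_d_cc + s_cb)/k_p_cc`` where both
branches equal the saturation velocity ``s_cb``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NoGrowthError,
    NoSaturationWarning,
)
from .model import Conditions, RateSet, rescale_rates, unit_convert

__all__ = [
    "CapDistribution",
    "VelocityPoint",
    "PhaseDiagram",
    "SwitchingRateEstimate",
    "cap_distribution",
    "q_probability",
    "filament_velocity",
    "beta_velocity",
    "saturation_velocity",
    "force_velocity_curve",
    "stall_force",
    "classify_phase",
    "phase_diagram",
    "estimate_switching_rate",
    "critical_velocity_default",
    "PHASE_LABELS",
    "PHASE_TOKENS",
]

#: canonical phase labels and their lowercase file tokens
PHASE_LABELS = ("no-aggregation", "disordered", "partially-ordered", "ordered")
PHASE_TOKENS = {
    "no-aggregation": "none",
    "disordered": "disordered",
    "partially-ordered": "partial",
    "ordered": "ordered",
}

_TAIL_TOL = 1e-12


def _ratios(rates: RateSet, conc: float):
    """Return (r, a): the cap-tail and empty-cap-escape ratios."""
    d_cc = rates.k_d_cc + rates.s_cb
    d_bc = rates.k_d_bc + rates.s_cb
    num_r = rates.k_p_cc * conc
    num_a = rates.k_p_bc * conc
    r = num_r / d_cc if num_r > 0 else 0.0
    a = num_a / d_bc if num_a > 0 else 0.0
    return r, a


def _conc_star(rates: RateSet) -> float:
    """Concentration where q reaches 1, found as the root of 1 - r(c)."""
    if rates.k_p_cc == 0:
        return math.inf
    # 1 - r(c) is linear in c; solve explicitly
    return (rates.k_d_cc + rates.s_cb) / rates.k_p_cc


def _conc_starstar(rates: RateSet) -> float:
    """Regime-1 ceiling: where the regime-2 line k_p_cc*c - k_d_cc = s_cb."""
    if rates.k_p_cc == 0:
        return math.inf
    return (rates.s_cb + rates.k_d_cc) / rates.k_p_cc


@dataclass(frozen=True)
class CapDistribution:
    """Steady-state cap-size distribution (regime 1) or its absence (regime 2).

    ``p[k]`` is the probability of k C monomers at the tip, truncated where
    the geometric tail mass drops below 1e-12 (``kmax`` = last index kept).
    In regime 2 the chain is transient toward large caps: ``stationary`` is
    False and ``p`` is empty.
    """

    p: np.ndarray
    q: float
    regime: int
    conc_star: float
    conc_starstar: float
    kmax: int
    stationary: bool

    def __post_init__(self):
        # the two crossover definitions must describe the same concentration
        if math.isfinite(self.conc_star) or math.isfinite(self.conc_starstar):
            if not math.isclose(
                self.conc_star, self.conc_starstar, rel_tol=1e-12, abs_tol=1e-12
            ):
                raise AssertionError(
                    "q->1 boundary and regime-2 crossing disagree: "
                    f"{self.conc_star} vs {self.conc_starstar}"
                )


def cap_distribution(
    rates: RateSet, conc: float, tail_tol: float = _TAIL_TOL
) -> CapDistribution:
    """Closed-form stationary distribution of the cap size.

    Raises :class:`~fibriltip.errors.NotAnalyticError` if ``s_bc`` or
    ``k_d_bb`` is nonzero.  For ``conc`` at or above the characteristic
    concentration the returned record is flagged non-stationary.
    """
    rates.require_analytic()
    if conc < 0:
        raise InvalidParameterError(f"conc must be >= 0, got {conc}")
    cs, css = _conc_star(rates), _conc_starstar(rates)
    r, a = _ratios(rates, conc)
    if r >= 1.0:
        return CapDistribution(
            p=np.empty(0), q=1.0, regime=2, conc_star=cs, conc_starstar=css,
            kmax=-1, stationary=False,
        )
    if a == 0.0:
        p = np.array([1.0])
        return CapDistribution(
            p=p, q=0.0, regime=1, conc_star=cs, conc_starstar=css,
            kmax=0, stationary=True,
        )
    p0 = (1.0 - r) / (1.0 - r + a)
    q = 1.0 - p0
    # tail mass beyond K (sum over k > K) is p0*a*r**K/(1-r); keep through K
    if r == 0.0:
        kmax = 1
    else:
        kmax = max(
            1,
            int(math.ceil(math.log(tail_tol * (1.0 - r) / (p0 * a)) / math.log(r))),
        )
        # near-critical r gives essentially unbounded geometric tails; clamp
        kmax = min(kmax, 1_000_000)
    k = np.arange(1, kmax + 1)
    p = np.empty(kmax + 1)
    p[0] = p0
    p[1:] = p0 * a * r ** (k - 1)
    return CapDistribution(
        p=p, q=q, regime=1, conc_star=cs, conc_starstar=css,
        kmax=kmax, stationary=True,
    )


def q_probability(rates: RateSet, conc: float) -> float:
    """Probability of at least one C monomer at the tip of a growing filament.

    ``q = a/(1 - r + a)`` below the characteristic concentration and exactly 1
    at or above it.
    """
    rates.require_analytic()
    if conc < 0:
        raise InvalidParameterError(f"conc must be >= 0, got {conc}")
    r, a = _ratios(rates, conc)
    if r >= 1.0:
        return 1.0
    if a == 0.0:
        return 0.0
    return a / (1.0 - r + a)


@dataclass(frozen=True)
class VelocityPoint:
    """Filament and beta-front growth velocities at one concentration."""

    conc: float
    v_f: float
    v_beta: float
    regime: int


def _regime1_velocity(rates: RateSet, conc: float) -> float:
    """Term-by-term stationary flux: B-end growth when the cap is empty plus
    C-on-C growth/shrinkage when it is not (enters through P_0 and P_1)."""
    r, a = _ratios(rates, conc)
    p0 = (1.0 - r) / (1.0 - r + a)
    p1 = p0 * a
    q = 1.0 - p0
    v = (
        p0 * rates.k_p_bc * conc
        + q * rates.k_p_cc * conc
        - p1 * rates.k_d_bc
        - (q - p1) * rates.k_d_cc
    )
    # the stationary flux is >= 0 analytically (= s_cb*q); cancellation in
    # the term sum can leave a tiny negative residue
    scale = rates.k_d_cc + rates.s_cb + 1.0
    if -1e-9 * scale < v < 0.0:
        v = 0.0
    return v


def _regime2_velocity(rates: RateSet, conc: float) -> float:
    """Cap-driven growth: the tip is never bare, so only C-on-C events count."""
    return rates.k_p_cc * conc - rates.k_d_cc


def _check_continuity(rates: RateSet) -> None:
    """The two velocity branches must agree at the regime boundary."""
    css = _conc_starstar(rates)
    if not math.isfinite(css):
        return
    scale = max(rates.s_cb, 1.0)
    c = css * (1.0 - 1e-13)  # just inside regime 1
    v1 = _regime1_velocity(rates, c)
    v2 = _regime2_velocity(rates, css)
    if abs(v1 - v2) > 1e-9 * scale:
        raise AssertionError(
            f"velocity branches discontinuous at [C]**={css}: {v1} vs {v2}"
        )


def filament_velocity(
    rates: RateSet, conc: float, cond: Optional[Conditions] = None
) -> VelocityPoint:
    """Mean filament elongation velocity, monomers/hr.

    If ``cond`` carries a nonzero force the rate constants are first passed
    through :func:`~fibriltip.model.rescale_rates`.  The regime is selected by
    the (rescaled) cap-tail ratio; both branches agree at the boundary, which
    is asserted on every call as a guard on the flux bookkeeping.
    """
    rates.require_analytic()
    if conc < 0:
        raise InvalidParameterError(f"conc must be >= 0, got {conc}")
    if cond is not None and cond.force > 0:
        rates = rescale_rates(rates, cond)
    _check_continuity(rates)
    r, _ = _ratios(rates, conc)
    if r >= 1.0:
        return VelocityPoint(conc, _regime2_velocity(rates, conc), rates.s_cb, 2)
    q = q_probability(rates, conc)
    return VelocityPoint(conc, _regime1_velocity(rates, conc), rates.s_cb * q, 1)


def beta_velocity(rates: RateSet, conc: float) -> float:
    """Growth velocity of the beta-sheet content, monomers/hr.

    Switching fires at ``s_cb`` whenever the cap is occupied, so
    ``v_beta = s_cb * q`` in regime 1 and exactly ``s_cb`` in regime 2; it can
    never exceed the switching rate.
    """
    rates.require_analytic()
    return rates.s_cb * q_probability(rates, conc)


def saturation_velocity(rates: RateSet) -> tuple[float, float]:
    """High-concentration regime-1 plateau and the concentration it occurs at.

    Returns ``(s_cb, conc_starstar)``: evaluating the regime-2 line at the
    regime-1 ceiling gives ``k_p_cc*[C]** - k_d_cc = s_cb`` — growth there is
    rate-limited by conformational switching alone.
    """
    rates.require_analytic()
    return rates.s_cb, _conc_starstar(rates)


def force_velocity_curve(
    rates: RateSet,
    conc: float,
    forces: Sequence[float],
    cond: Optional[Conditions] = None,
) -> list[tuple[float, float]]:
    """Velocity against an ascending sequence of opposing loads (pN)."""
    forces = list(forces)
    if any(f < 0 for f in forces):
        raise InvalidParameterError("forces must all be >= 0")
    if any(b < a for a, b in zip(forces, forces[1:])):
        raise InvalidParameterError("forces must be sorted ascending")
    base = cond if cond is not None else Conditions(conc=conc)
    return [
        (F, filament_velocity(rates, conc, base.replace(force=F)).v_f)
        for F in forces
    ]


def stall_force(
    rates: RateSet,
    conc: float,
    cond: Optional[Conditions] = None,
    tol: float = 1e-3,
    stall_fraction: float = 0.05,
) -> float:
    """Operational stall force: the load at which growth effectively ceases.

    Because the beta core never depolymerizes, the loaded velocity
    ``v(F) = s_cb*q(F)`` stays strictly positive at any finite force and only
    vanishes asymptotically; the mathematical root ``v(F) = 0`` does not
    exist.  What the force-velocity curve shows instead is a steep collapse
    once the load pushes the tip out of the cap-driven regime.  The stall
    force is therefore defined as the load at which velocity first falls to
    ``stall_fraction`` of its unloaded value (default 5%, an effective
    detection threshold), located by doubling-bracket plus bisection to a
    force tolerance ``tol`` (pN).
    """
    if not 0 < stall_fraction < 1:
        raise InvalidParameterError("stall_fraction must be in (0, 1)")
    base = cond if cond is not None else Conditions(conc=conc)
    v0 = filament_velocity(rates, conc, base.replace(force=0.0)).v_f
    if v0 <= 0:
        raise NoGrowthError(
            f"unloaded velocity is {v0} <= 0 at conc={conc}; stall undefined"
        )
    target = stall_fraction * v0

    def g(F):
        return filament_velocity(rates, conc, base.replace(force=F)).v_f - target

    hi = 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e7:  # pragma: no cover - defensive
            raise NoGrowthError("no stall bracket found below 1e7 pN")
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def critical_velocity_default(rise: float = 0.5) -> float:
    """0.5 um/day — the smallest growth visible by light microscopy — in
    monomers/hr."""
    return unit_convert(0.5, "um/day", "monomers/hr", rise=rise)


def classify_phase(v_f: float, v_beta: float, v_c: float) -> str:
    """Kinetic phase of a (v_f, v_beta) point against a critical velocity.

    * ``no-aggregation``     v_f < v_c (nothing visible grows);
    * ``disordered``         v_f >= v_c but v_beta < v_c (aggregate grows,
      beta content does not);
    * ``partially-ordered``  both exceed v_c and v_f > 2*v_beta (beta content
      lags the aggregate by more than a factor two);
    * ``ordered``            both exceed v_c and v_f <= 2*v_beta.
    """
    if v_f < 0 or v_beta < 0 or v_c < 0:
        raise InvalidParameterError("velocities must be >= 0")
    if v_f < v_c:
        return "no-aggregation"
    if v_beta < v_c:
        return "disordered"
    if v_f > 2.0 * v_beta:
        return "partially-ordered"
    return "ordered"


@dataclass(frozen=True)
class PhaseDiagram:
    """Phase labels over a (switching rate, concentration) grid.

    ``labels[i, j]`` classifies ``s_cb_grid[i]`` x ``conc_grid[j]``.  The
    ``boundary_*`` arrays hold, per switching rate, the concentration at which
    each boundary condition is crossed (NaN where it is not crossed on the
    grid span); together they trace the level sets v_f = v_c, v_beta = v_c and
    v_f = 2*v_beta.
    """

    s_cb_grid: np.ndarray
    conc_grid: np.ndarray
    v_f: np.ndarray
    v_beta: np.ndarray
    labels: np.ndarray
    v_c: float
    boundary_vf: np.ndarray = field(default=None)
    boundary_vbeta: np.ndarray = field(default=None)
    boundary_partial: np.ndarray = field(default=None)


def _crossing_conc(fun, c_lo, c_hi, n=200):
    """First concentration in [c_lo, c_hi] where monotone-ish fun crosses 0."""
    grid = np.geomspace(max(c_lo, 1e-12), c_hi, n)
    vals = np.array([fun(c) for c in grid])
    sign = vals > 0
    idx = np.nonzero(sign[1:] != sign[:-1])[0]
    if idx.size == 0:
        return math.nan
    i = idx[0]
    return optimize.brentq(fun, grid[i], grid[i + 1])


def phase_diagram(
    rates_template: RateSet,
    s_cb_grid: Sequence[float],
    conc_grid: Sequence[float],
    v_c: Optional[float] = None,
) -> PhaseDiagram:
    """Label every (s_cb, conc) grid point by its kinetic phase."""
    s_grid = np.asarray(list(s_cb_grid), dtype=float)
    c_grid = np.asarray(list(conc_grid), dtype=float)
    if s_grid.size == 0 or c_grid.size == 0:
        raise InvalidParameterError("grids must be nonempty")
    if v_c is None:
        v_c = critical_velocity_default()
    vf = np.empty((s_grid.size, c_grid.size))
    vb = np.empty_like(vf)
    labels = np.empty(vf.shape, dtype=object)
    b_vf = np.full(s_grid.size, math.nan)
    b_vb = np.full(s_grid.size, math.nan)
    b_pa = np.full(s_grid.size, math.nan)
    for i, s in enumerate(s_grid):
        rates = rates_template.replace(s_cb=float(s))
        for j, c in enumerate(c_grid):
            pt = filament_velocity(rates, float(c))
            vf[i, j] = pt.v_f
            vb[i, j] = pt.v_beta
            labels[i, j] = classify_phase(pt.v_f, pt.v_beta, v_c)
        c_lo, c_hi = c_grid.min(), c_grid.max()
        b_vf[i] = _crossing_conc(
            lambda c: filament_velocity(rates, c).v_f - v_c, c_lo, c_hi
        )
        b_vb[i] = _crossing_conc(
            lambda c: beta_velocity(rates, c) - v_c, c_lo, c_hi
        )
        b_pa[i] = _crossing_conc(
            lambda c: (lambda p: p.v_f - 2.0 * p.v_beta)(filament_velocity(rates, c)),
            c_lo,
            c_hi,
        )
    return PhaseDiagram(
        s_cb_grid=s_grid, conc_grid=c_grid, v_f=vf, v_beta=vb, labels=labels,
        v_c=v_c, boundary_vf=b_vf, boundary_vbeta=b_vb, boundary_partial=b_pa,
    )


@dataclass(frozen=True)
class SwitchingRateEstimate:
    """Switching rate recovered from a concentration-velocity curve."""

    s_cb: float
    ci: tuple[float, float]
    method: str  # "model-fit", "plateau", or "lower-bound"
    saturated: bool


def _plateau_estimate(conc, v, saturated, n_top=3):
    top = np.argsort(conc)[-n_top:]
    vals = v[top]
    mean = float(vals.mean())
    if len(vals) > 1 and vals.std(ddof=1) > 0:
        sem = vals.std(ddof=1) / math.sqrt(len(vals))
        half = stats.t.ppf(0.975, len(vals) - 1) * sem
    else:
        half = 0.0
    return SwitchingRateEstimate(
        s_cb=mean,
        ci=(mean - half, mean + half),
        method="plateau" if saturated else "lower-bound",
        saturated=saturated,
    )


def _q_model(c, s, A, R):
    """Regime-1 velocity surface v = s*q with lumped ratios a=A*c, r=R*c,
    clamped to the saturation value past the regime boundary."""
    c = np.asarray(c, dtype=float)
    one_minus_r = np.clip(1.0 - R * c, 0.0, None)
    a = A * c
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(a + one_minus_r > 0, a / (one_minus_r + a), 1.0)
    return s * q


def estimate_switching_rate(
    curve: Sequence[tuple[float, float]],
) -> SwitchingRateEstimate:
    """Estimate s_cb from a (conc, velocity) curve via its regime-1 plateau.

    The saturation velocity of the two-state model equals the switching rate,
    so fitting ``v(c) = s*q(c)`` with lumped ratio parameters recovers s_cb
    directly; when the fit is ill-conditioned a robust top-concentration
    plateau mean (with Student CI) is used instead.  Velocities must already
    be in monomers/hr.

    If the curve is still rising at the top concentration (slope of the last
    three points >= 5% of the maximum slope) a
    :class:`~fibriltip.errors.NoSaturationWarning` is emitted and the estimate
    is only a lower bound.
    """
    pts = sorted((float(c), float(v)) for c, v in curve)
    if len(pts) < 4:
        raise InsufficientDataError("need at least 4 (conc, velocity) points")
    conc = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    slopes = np.diff(v) / np.diff(conc)
    max_slope = np.abs(slopes).max()
    tail_slope = (v[-1] - v[-3]) / (conc[-1] - conc[-3])
    saturated = max_slope == 0 or abs(tail_slope) < 0.05 * max_slope
    if not saturated:
        warnings.warn(
            "velocity curve still rising at the top concentration; "
            "reported switching rate is a lower bound",
            NoSaturationWarning,
        )
        return _plateau_estimate(conc, v, saturated)
    if np.allclose(v, v[0]):
        return SwitchingRateEstimate(
            s_cb=float(v.mean()), ci=(float(v.mean()), float(v.mean())),
            method="plateau", saturated=True,
        )
    try:
        vmax = v.max()
        p0 = (vmax, 1.0 / conc.mean(), 0.5 / conc.max())
        popt, pcov = optimize.curve_fit(
            _q_model, conc, v, p0=p0,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        s_hat = float(popt[0])
        s_err = float(np.sqrt(pcov[0, 0]))
        if not (np.isfinite(s_hat) and np.isfinite(s_err)):
            raise RuntimeError("ill-conditioned fit")
        return SwitchingRateEstimate(
            s_cb=s_hat,
            ci=(s_hat - 1.96 * s_err, s_hat + 1.96 * s_err),
            method="model-fit",
            saturated=True,
        )
    except (RuntimeError, ValueError):
        return _plateau_estimate(conc, v, saturated=True)
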