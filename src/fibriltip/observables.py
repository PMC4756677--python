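"""Estimators turning trajectories and ensembles into measurable quantities.

Covers the quantities a single-filament experiment reports: steady and
initial elongation velocities, ensemble length heterogeneity sigma(t) and the
time tau at which it peaks, the tau-versus-switching-rate relation, and
stop-and-go dwell statistics at the conventional 2 nm/min threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError
from .kmc import EnsembleStats, Trajectory, run_ensemble
from .model import RateSet, unit_convert
from .theory import q_probability

__all__ = [
    "VelocityEstimate",
    "HeterogeneityCurve",
    "DwellSegments",
    "DwellStatistics",
    "steady_velocity",
    "ensemble_velocity",
    "initial_velocity",
    "length_heterogeneity",
    "tau_vs_switching",
    "segment_stop_go",
    "dwell_statistics",
    "STOP_THRESHOLD_DEFAULT",
    "STOP_WINDOW_DEFAULT",
    "STOP_SPAN_DEFAULT",
]

#: stop/go velocity cutoff: 2 nm/min in monomers/hr at the default rise
STOP_THRESHOLD_DEFAULT = unit_convert(2.0, "nm/min", "monomers/hr")  # 240.0
#: stop/go analysis window, hours (10 min)
STOP_WINDOW_DEFAULT = 1.0 / 6.0
#: stop/go analysis span, hours
STOP_SPAN_DEFAULT = 60.0


@dataclass(frozen=True)
class VelocityEstimate:
    value: float  # monomers/hr
    se: float
    n: int


def steady_velocity(traj: Trajectory, t_min: float = 0.0) -> VelocityEstimate:
    """Least-squares slope of length vs time for ``t >= t_min``.

    The standard error comes from the OLS residuals; note that event-time
    samples of a growth process are autocorrelated, so for ensemble work
    prefer the spread of per-run slopes (:func:`ensemble_velocity`).
    """
    mask = traj.times >= t_min
    t = traj.times[mask]
    y = traj.length[mask].astype(float)
    if t.size < 3:
        raise InsufficientDataError(
            f"only {t.size} points at t >= {t_min}; need >= 3"
        )
    if np.ptp(t) == 0:
        raise InsufficientDataError("degenerate time span after t_min")
    (slope, icept), cov = np.polyfit(t, y, 1, cov=True)
    return VelocityEstimate(float(slope), float(math.sqrt(cov[0, 0])), t.size)


def ensemble_velocity(
    trajs_or_stats, t_min: float = 0.0
) -> VelocityEstimate:
    """Mean growth velocity of an ensemble with a between-run standard error.

    Accepts either a list of trajectories or an :class:`EnsembleStats` with
    its per-run length matrix; the estimate is the mean of per-run
    least-squares slopes and the SE their spread / sqrt(n).
    """
    if isinstance(trajs_or_stats, EnsembleStats):
        st = trajs_or_stats
        if st.lengths is None:
            raise InsufficientDataError("EnsembleStats lacks per-run lengths")
        mask = st.time_grid >= t_min
        if mask.sum() < 3:
            raise InsufficientDataError("too few grid points after t_min")
        t = st.time_grid[mask]
        slopes = np.polyfit(t, st.lengths[:, mask].T, 1)[0]
    else:
        slopes = np.array(
            [steady_velocity(tr, t_min).value for tr in trajs_or_stats]
        )
    n = slopes.size
    if n < 2:
        raise InsufficientDataError("need >= 2 runs for an ensemble velocity")
    return VelocityEstimate(
        float(slopes.mean()), float(slopes.std(ddof=1) / math.sqrt(n)), n
    )


def initial_velocity(traj: Trajectory) -> float:
    """Average velocity until the filament reaches 10% of its maximum length.

    ``(L(t10) - L(0)) / t10`` with t10 the first time length reaches 10% of
    the run's maximum — the early-growth estimator used for mass-conserved
    (depleting) runs, where the late plateau makes a global slope meaningless.
    """
    L = traj.length.astype(float)
    target = 0.1 * L.max()
    if L[0] >= target or L.max() <= L[0]:
        raise InsufficientDataError(
            "initial velocity undefined: seed already exceeds 10% of the "
            "maximum length (flat or degenerate run)"
        )
    i = int(np.argmax(L >= target))
    t10 = traj.times[i]
    if t10 <= 0:
        raise InsufficientDataError("degenerate t10 = 0")
    return float((L[i] - L[0]) / t10)


@dataclass(frozen=True)
class HeterogeneityCurve:
    """Ensemble length spread sigma(t) and the time of its (smoothed) peak."""

    time_grid: np.ndarray
    sigma: np.ndarray
    sigma_smooth: np.ndarray
    tau_max: Optional[float]  # None when sigma is identically ~0
    cv: np.ndarray  # sigma / mean length, convenience column
    n_runs: int


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.copy()
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + x.size]
    return out


def length_heterogeneity(
    ensemble: EnsembleStats, smoothing_window: int = 5
) -> HeterogeneityCurve:
    """Population standard deviation of length across realizations.

    ``sigma(t) = sqrt(<L^2> - <L>^2)`` over the ensemble; ``tau_max`` is the
    grid time of the maximum of the centred-moving-average-smoothed sigma
    (default 5 grid points), or None for a degenerate (sigma ~ 0) ensemble.
    """
    if ensemble.n_runs < 2:
        raise InsufficientDataError("need >= 2 runs for a heterogeneity curve")
    if ensemble.n_runs < 20:
        warnings.warn(
            f"only {ensemble.n_runs} runs; sigma(t) and tau will be noisy",
            stacklevel=2,
        )
    sigma = ensemble.sigma
    smooth = _moving_average(sigma, smoothing_window)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(ensemble.mean_length > 0, sigma / ensemble.mean_length, 0.0)
    if sigma.max() <= 1e-12:
        tau = None
    else:
        tau = float(ensemble.time_grid[int(np.argmax(smooth))])
    return HeterogeneityCurve(
        time_grid=ensemble.time_grid, sigma=sigma, sigma_smooth=smooth,
        tau_max=tau, cv=cv, n_runs=ensemble.n_runs,
    )


@dataclass(frozen=True)
class TauSweep:
    """tau_max against switching rate with its log-log slope."""

    s_cb: np.ndarray
    tau: np.ndarray
    slope: float
    slope_ci: tuple[float, float]


def tau_vs_switching(
    rates_template: RateSet,
    s_cb_values: Sequence[float],
    conc0: float,
    n_total: int,
    n_runs: int = 24,
    base_rng_seed: int = 0,
    grid_points: int = 400,
    span_factor: float = 3.0,
    smoothing_window: int = 5,
) -> TauSweep:
    """Peak-heterogeneity time tau against the switching rate (mass-conserved).

    For each switching rate an independent mass-conserved ensemble is run to
    ``span_factor`` times the expected depletion time ``n_total / v(conc0)``
    (so slow switchers get proportionally longer windows), sigma(t) computed,
    and the log-log slope of tau vs s_cb fit by least squares with a 95% CI.
    Sweep values with an undefined tau are dropped with a warning.
    """
    svals = np.asarray(list(s_cb_values), dtype=float)
    if svals.size < 4 or svals.max() / svals.min() < 10.0:
        raise InvalidParameterError(
            "need >= 4 switching rates spanning at least one decade"
        )
    taus = []
    kept = []
    for i, s in enumerate(svals):
        rates = rates_template.replace(s_cb=float(s))
        v0 = s * q_probability(rates, conc0)
        if v0 <= 0:
            warnings.warn(f"s_cb={s}: no growth; dropped", stacklevel=2)
            continue
        t_end = span_factor * n_total / v0
        grid = np.linspace(0.0, t_end, grid_points)
        stats_, _ = run_ensemble(
            rates, conc0, t_end, grid, n_runs,
            base_rng_seed=base_rng_seed + 10_000 * i,
            mode="mass-conserved", n_total=n_total,
        )
        het = length_heterogeneity(stats_, smoothing_window)
        if het.tau_max is None or het.tau_max <= 0:
            warnings.warn(f"s_cb={s}: tau undefined; dropped", stacklevel=2)
            continue
        taus.append(het.tau_max)
        kept.append(s)
    if len(kept) < 3:
        raise InsufficientDataError("fewer than 3 usable tau points")
    x = np.log(np.asarray(kept))
    y = np.log(np.asarray(taus))
    res = stats.linregress(x, y)
    half = stats.t.ppf(0.975, len(kept) - 2) * res.stderr if len(kept) > 2 else np.inf
    return TauSweep(
        s_cb=np.asarray(kept), tau=np.asarray(taus),
        slope=float(res.slope),
        slope_ci=(float(res.slope - half), float(res.slope + half)),
    )


@dataclass(frozen=True)
class DwellSegments:
    """Alternating stop/go segments tiling the analysis interval."""

    segments: list  # of (t_start, t_end, phase) with phase in {"stop", "go"}
    threshold: float  # monomers/hr
    window: float  # hours
    span: float  # hours analysed

    def durations(self, phase: str, interior_only: bool = True) -> np.ndarray:
        """Segment durations for one phase.

        ``interior_only`` drops the first and last segment of the record,
        which are censored by the analysis boundaries.
        """
        segs = self.segments[1:-1] if interior_only else self.segments
        return np.array([b - a for a, b, ph in segs if ph == phase])


def segment_stop_go(
    traj: Trajectory,
    threshold: Optional[float] = None,
    window: float = STOP_WINDOW_DEFAULT,
    t_max: float = STOP_SPAN_DEFAULT,
) -> DwellSegments:
    """Threshold a trajectory into stop and go phases.

    The trajectory is cut into consecutive windows (default 10 min) over the
    first ``t_max`` hours (default 60 h); a window whose forward length
    difference corresponds to a growth rate below ``threshold`` (default
    2 nm/min = 240 monomers/hr at 2 monomers/nm) is a stop, otherwise a go.
    Adjacent same-phase windows are merged, so the segments tile the analysis
    interval exactly and alternate in phase.
    """
    if threshold is None:
        threshold = STOP_THRESHOLD_DEFAULT
    span = min(t_max, traj.times[-1])
    if span < 2 * window:
        raise InsufficientDataError(
            f"trajectory span {span} h is shorter than two windows"
        )
    nwin = int(span // window)
    edges = np.arange(nwin + 1) * window
    L = traj.length_at(edges)
    vel = np.diff(L) / window
    phases = np.where(vel < threshold, "stop", "go")
    segments = []
    start = 0
    for i in range(1, nwin + 1):
        if i == nwin or phases[i] != phases[start]:
            segments.append((edges[start], edges[i], str(phases[start])))
            start = i
    return DwellSegments(
        segments=segments, threshold=threshold, window=window,
        span=float(edges[-1]),
    )


@dataclass(frozen=True)
class PhaseFit:
    n: int
    rate: float  # /hr, maximum-likelihood exponential rate
    mean: float  # hr
    ks_stat: float
    ks_p: float


@dataclass(frozen=True)
class DwellStatistics:
    go: PhaseFit
    stop: PhaseFit
    similarity_ks_stat: float
    similarity_p: float
    go_durations: np.ndarray
    stop_durations: np.ndarray


def _fit_phase(durations: np.ndarray, dead_time: float) -> PhaseFit:
    """Shifted-exponential MLE with a detection dead time.

    Windowed segmentation cannot observe dwells shorter than one window and
    reports durations on a window lattice, so the fitted model is an
    exponential shifted by ``dead_time`` (default half a window — the lattice
    continuity correction standard in single-molecule dwell analysis); the
    memorylessness being tested is unaffected by the shift.
    """
    mean = float(durations.mean())
    scale = mean - dead_time
    if scale <= 0:
        raise InsufficientDataError("dwells shorter than the dead time")
    ks = stats.kstest(durations, "expon", args=(dead_time, scale))
    return PhaseFit(
        n=durations.size, rate=1.0 / scale, mean=mean,
        ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
    )


def dwell_statistics(
    segments_collection: Sequence[DwellSegments],
    min_dwells: int = 50,
    dead_time: Optional[float] = None,
) -> DwellStatistics:
    """Pooled dwell-time statistics across an ensemble of segmentations.

    Interior (uncensored) dwell durations are pooled per phase; each phase
    gets a maximum-likelihood exponential fit (rate = 1/(mean - dead time),
    dead time defaulting to half the segmentation window) with a one-sample
    Kolmogorov-Smirnov statistic against that fit, and the go/stop similarity
    is measured by a two-sample KS test.
    """
    if dead_time is None:
        dead_time = 0.5 * segments_collection[0].window
    go = np.concatenate([s.durations("go") for s in segments_collection])
    stop = np.concatenate([s.durations("stop") for s in segments_collection])
    if go.size < min_dwells or stop.size < min_dwells:
        raise InsufficientDataError(
            f"need >= {min_dwells} dwells per phase, got go={go.size}, "
            f"stop={stop.size}"
        )
    two = stats.ks_2samp(go, stop)
    return DwellStatistics(
        go=_fit_phase(go, dead_time), stop=_fit_phase(stop, dead_time),
        similarity_ks_stat=float(two.statistic),
        similarity_p=float(two.pvalue),
        go_durations=go, stop_durations=stop,
    )
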