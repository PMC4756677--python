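"""Gillespie (kinetic Monte Carlo) simulation of single-filament growth.

Three setups are provided, mirroring how aggregation experiments are run:

* :func:`simulate_constant_c` — the free monomer pool is held fixed (flow
  cell / large reservoir);
* :func:`simulate_mass_conserved` — free plus polymerized monomers sum to a
  fixed total, so the pool depletes as the filament grows;
* :func:`simulate_with_fragmentation` — constant concentration with an
  additional per-bond breakage channel that spawns new, independently
  growing seeds.

The single-filament event set is exactly the model's: C-on-C and C-on-B
polymerization, the matching depolymerizations, forward (C->B, leftmost C)
and backward (B->C, rightmost B) switching, and optional B-B depolymerization
for exploratory runs.  In seeded mode the beta core never drops below one
monomer, matching the established-filament premise of the tip-cap master
equation.

The hot loops are numba-compiled; every run is exactly reproducible from its
``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .errors import InvalidParameterError
from .model import FilamentState, RateSet

__all__ = [
    "Trajectory",
    "EnsembleStats",
    "EVENT_NAMES",
    "simulate_constant_c",
    "simulate_mass_conserved",
    "simulate_with_fragmentation",
    "run_ensemble",
]

#: event-code legend for ``Trajectory.event_codes``
EVENT_NAMES = (
    "polymerize-CC",    # 0: cap >= 1, k += 1
    "polymerize-BC",    # 1: cap == 0, k += 1
    "depolymerize-CC",  # 2: cap >= 2, k -= 1
    "depolymerize-BC",  # 3: cap == 1, k -= 1
    "switch-CB",        # 4: cap >= 1, k -= 1, n_beta += 1
    "switch-BC",        # 5: n_beta >= 2, k += 1, n_beta -= 1
    "depolymerize-BB",  # 6: cap == 0, n_beta >= 2, n_beta -= 1
    "fragment",         # 7: filament splits at a B-B bond
)


@dataclass
class Trajectory:
    """Event-resolved time series of one filament.

    ``times[0] = 0`` holds the initial state; every later entry is the state
    *after* one event.  ``early_stop`` marks runs that ran out of possible
    events before ``t_end``.
    """

    times: np.ndarray
    n_beta: np.ndarray
    cap_k: np.ndarray
    rng_seed: int
    t_end: float
    filament_id: int = 0
    parent_id: Optional[int] = None
    born: float = 0.0
    event_codes: Optional[np.ndarray] = None
    early_stop: bool = False
    mode: str = "constant-c"

    @property
    def length(self) -> np.ndarray:
        return self.n_beta + self.cap_k

    @property
    def n_events(self) -> int:
        return len(self.times) - 1

    def split_at_fragmentations(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Split the record into stretches between fragmentation events.

        Fragmentation changes length discontinuously (mass moves to a
        daughter), so growth velocities are only meaningful within a stretch.
        Returns (times, lengths) pairs; a trajectory without fragmentation
        events yields a single stretch.
        """
        L = self.length
        if self.event_codes is None or not (self.event_codes == 7).any():
            return [(self.times, L)]
        # event_codes[i] produced state i+1
        cuts = np.nonzero(self.event_codes == 7)[0] + 1
        out = []
        start = 0
        for c in list(cuts) + [len(self.times)]:
            if c - start >= 2:
                out.append((self.times[start:c], L[start:c]))
            start = c
        return out

    def length_at(self, t_grid: np.ndarray) -> np.ndarray:
        """Length sampled on ``t_grid`` (last value carried forward)."""
        t_grid = np.asarray(t_grid, dtype=float)
        idx = np.searchsorted(self.times, t_grid, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        out = (self.n_beta + self.cap_k)[idx].astype(float)
        out[t_grid < self.born] = np.nan
        return out


@dataclass
class EnsembleStats:
    """Ensemble mean and spread of filament length on a common time grid."""

    time_grid: np.ndarray
    mean_length: np.ndarray
    sigma: np.ndarray  # population standard deviation across runs
    n_runs: int
    lengths: Optional[np.ndarray] = None  # (n_runs, len(time_grid))
    n_beta: Optional[np.ndarray] = None


@njit(cache=True)
def _sim_kernel(
    rng,
    kpcc, kpbc, kdcc, kdbc, scb, sbc, kdbb,
    conc0, nfree0, mass_conserved,
    t0, t_end, m0, k0, nfree_in,
    times, nbeta_out, cap_out, codes,
    grid, grid_len_out, grid_beta_out, grid_start,
):
    """Shared Gillespie core.

    Records every event into ``times``/``nbeta_out``/``cap_out``/``codes`` up
    to their capacity (pass length-0 arrays to skip) and/or samples the state
    onto ``grid`` by last-value-carried-forward (pass length-0 grid to skip).
    Returns (n_recorded, t, m, k, nfree, gi, status) with status 0 = reached
    t_end, 1 = all propensities vanished, 2 = event capacity hit (resume me).
    """
    t = t0
    m = m0
    k = k0
    nfree = nfree_in
    nev = 0
    cap_events = times.shape[0]
    gi = grid_start
    ng = grid.shape[0]
    status = 0
    while True:
        if mass_conserved:
            c = conc0 * nfree / nfree0
        else:
            c = conc0
        a1 = kpcc * c if k >= 1 else 0.0
        a2 = kpbc * c if k == 0 else 0.0
        a3 = kdcc if k >= 2 else 0.0
        a4 = kdbc if k == 1 else 0.0
        a5 = scb if k >= 1 else 0.0
        a6 = sbc if m >= 2 else 0.0
        a7 = kdbb if (k == 0 and m >= 2) else 0.0
        rtot = a1 + a2 + a3 + a4 + a5 + a6 + a7
        if rtot <= 0.0:
            status = 1
            break
        dt = -np.log(rng.random()) / rtot
        t_new = t + dt
        if t_new > t_end:
            t = t_end
            break
        # sample the pre-event state onto grid points passed by this jump
        while gi < ng and grid[gi] < t_new:
            grid_len_out[gi] = m + k
            grid_beta_out[gi] = m
            gi += 1
        t = t_new
        u = rng.random() * rtot
        if u < a1:
            code = 0; k += 1; nfree -= 1
        elif u < a1 + a2:
            code = 1; k += 1; nfree -= 1
        elif u < a1 + a2 + a3:
            code = 2; k -= 1; nfree += 1
        elif u < a1 + a2 + a3 + a4:
            code = 3; k -= 1; nfree += 1
        elif u < a1 + a2 + a3 + a4 + a5:
            code = 4; k -= 1; m += 1
        elif u < a1 + a2 + a3 + a4 + a5 + a6:
            code = 5; k += 1; m -= 1
        else:
            code = 6; m -= 1; nfree += 1
        if nev < cap_events:
            times[nev] = t
            nbeta_out[nev] = m
            cap_out[nev] = k
            codes[nev] = code
            nev += 1
            if nev == cap_events:
                status = 2
                break
        # event recording disabled (cap_events == 0): keep going
    # fill remaining grid points with the final state
    while gi < ng and grid[gi] <= t_end:
        grid_len_out[gi] = m + k
        grid_beta_out[gi] = m
        gi += 1
    return nev, t, m, k, nfree, gi, status


_EMPTY_F = np.empty(0, dtype=np.float64)
_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_I8 = np.empty(0, dtype=np.int8)


def _run(
    rates: RateSet,
    conc: float,
    t_end: float,
    seed_state: FilamentState,
    rng_seed: int,
    mass_conserved: bool,
    n_total: Optional[int],
    record_events: bool,
    time_grid: Optional[np.ndarray],
    mode: str,
):
    if t_end <= 0:
        raise InvalidParameterError(f"t_end must be > 0, got {t_end}")
    if conc < 0:
        raise InvalidParameterError(f"conc must be >= 0, got {conc}")
    if seed_state.n_beta < 1:
        raise InvalidParameterError("seeded mode requires n_beta >= 1")
    if mass_conserved:
        if n_total is None or n_total <= seed_state.length:
            raise InvalidParameterError(
                f"n_total must exceed the seed length {seed_state.length}"
            )
        nfree0 = n_total - seed_state.length
    else:
        nfree0 = 1  # unused divisor
    rng = np.random.default_rng(rng_seed)
    if time_grid is None:
        grid = _EMPTY_F
        glen = _EMPTY_I
        gbeta = _EMPTY_I
    else:
        grid = np.asarray(time_grid, dtype=np.float64)
        glen = np.zeros(grid.shape, dtype=np.int64)
        gbeta = np.zeros(grid.shape, dtype=np.int64)

    chunks = []
    t, m, k = 0.0, seed_state.n_beta, seed_state.cap_k
    nfree = nfree0
    gi = 0
    early = False
    if record_events:
        chunk = 1 << 16
        while True:
            times = np.empty(chunk)
            nb = np.empty(chunk, dtype=np.int64)
            ck = np.empty(chunk, dtype=np.int64)
            codes = np.empty(chunk, dtype=np.int8)
            nev, t, m, k, nfree, gi, status = _sim_kernel(
                rng, rates.k_p_cc, rates.k_p_bc, rates.k_d_cc, rates.k_d_bc,
                rates.s_cb, rates.s_bc, rates.k_d_bb,
                conc, float(nfree0), mass_conserved,
                t, t_end, m, k, nfree,
                times, nb, ck, codes, grid, glen, gbeta, gi,
            )
            chunks.append((times[:nev], nb[:nev], ck[:nev], codes[:nev]))
            if status != 2:
                early = status == 1
                break
            chunk = min(2 * chunk, 1 << 22)
        times = np.concatenate([np.zeros(1)] + [c[0] for c in chunks])
        nb = np.concatenate(
            [np.array([seed_state.n_beta])] + [c[1] for c in chunks]
        )
        ck = np.concatenate([np.array([seed_state.cap_k])] + [c[2] for c in chunks])
        codes = np.concatenate([c[3] for c in chunks]) if chunks else _EMPTY_I8
    else:
        nev, t, m, k, nfree, gi, status = _sim_kernel(
            rng, rates.k_p_cc, rates.k_p_bc, rates.k_d_cc, rates.k_d_bc,
            rates.s_cb, rates.s_bc, rates.k_d_bb,
            conc, float(nfree0), mass_conserved,
            t, t_end, m, k, nfree,
            _EMPTY_F, _EMPTY_I, _EMPTY_I, _EMPTY_I8, grid, glen, gbeta, gi,
        )
        early = status == 1
        times = np.array([0.0, t])
        nb = np.array([seed_state.n_beta, m])
        ck = np.array([seed_state.cap_k, k])
        codes = None
    traj = Trajectory(
        times=times, n_beta=nb, cap_k=ck, rng_seed=rng_seed, t_end=t_end,
        event_codes=codes, early_stop=early, mode=mode,
    )
    return traj, glen, gbeta, (m, k, int(nfree))


def simulate_constant_c(
    rates: RateSet,
    conc: float,
    t_end: float,
    seed_state: FilamentState = FilamentState(1, 0),
    rng_seed: int = 0,
    record_events: bool = True,
) -> Trajectory:
    """Exact stochastic simulation at fixed free-monomer concentration."""
    traj, _, _, _ = _run(
        rates, conc, t_end, seed_state, rng_seed,
        mass_conserved=False, n_total=None,
        record_events=record_events, time_grid=None, mode="constant-c",
    )
    return traj


def simulate_mass_conserved(
    rates: RateSet,
    conc0: float,
    n_total: int,
    t_end: float,
    seed_state: FilamentState = FilamentState(1, 0),
    rng_seed: int = 0,
    record_events: bool = True,
) -> Trajectory:
    """Stochastic simulation with a conserved monomer pool.

    The instantaneous concentration is ``conc0 * n_free / n_free(0)`` with
    ``n_free(0) = n_total - seed length``; polymerization decrements the free
    pool and depolymerization returns monomers to it, so
    ``n_free + length = n_total`` holds exactly after every event (length can
    be recovered as ``n_total - n_free`` at any time).
    """
    traj, _, _, _ = _run(
        rates, conc0, t_end, seed_state, rng_seed,
        mass_conserved=True, n_total=n_total,
        record_events=record_events, time_grid=None, mode="mass-conserved",
    )
    return traj


def run_ensemble(
    rates: RateSet,
    conc: float,
    t_end: float,
    time_grid: np.ndarray,
    n_runs: int,
    base_rng_seed: int = 0,
    mode: str = "constant-c",
    n_total: Optional[int] = None,
    seed_state: FilamentState = FilamentState(1, 0),
    keep_trajectories: bool = False,
) -> tuple[EnsembleStats, list[Trajectory]]:
    """Independent replicate runs sampled onto a common time grid.

    Run ``i`` uses seed ``base_rng_seed + i``; the same base seed reproduces
    the ensemble bit for bit.  Lengths are step functions between events, so
    grid sampling carries the last value forward.  Returns population
    mean/sigma of length over runs and (optionally) the full event-resolved
    trajectories.
    """
    if n_runs < 2:
        raise InvalidParameterError("n_runs must be >= 2")
    time_grid = np.asarray(time_grid, dtype=float)
    mass = mode == "mass-conserved"
    if mode not in ("constant-c", "mass-conserved"):
        raise InvalidParameterError(f"unknown ensemble mode {mode!r}")
    lengths = np.empty((n_runs, time_grid.size))
    betas = np.empty((n_runs, time_grid.size))
    trajs: list[Trajectory] = []
    for i in range(n_runs):
        traj, glen, gbeta, _ = _run(
            rates, conc, t_end, seed_state, base_rng_seed + i,
            mass_conserved=mass, n_total=n_total,
            record_events=keep_trajectories, time_grid=time_grid, mode=mode,
        )
        lengths[i] = glen
        betas[i] = gbeta
        if keep_trajectories:
            traj.filament_id = i
            trajs.append(traj)
    stats = EnsembleStats(
        time_grid=time_grid,
        mean_length=lengths.mean(axis=0),
        sigma=lengths.std(axis=0),  # population (ensemble-moment) sigma
        n_runs=n_runs,
        lengths=lengths,
        n_beta=betas,
    )
    return stats, trajs


# ---------------------------------------------------------------------------
# fragmentation


def simulate_with_fragmentation(
    rates: RateSet,
    conc: float,
    k_frag: float,
    t_end: float,
    rng_seed: int = 0,
    seed_state: FilamentState = FilamentState(1, 0),
    bonds: str = "bb",
) -> list[Trajectory]:
    """Constant-concentration growth with stochastic fibril breakage.

    Each filament contributes a fragmentation propensity ``k_frag`` per
    eligible bond (``bonds="bb"``: B-B bonds only, the default — cap bonds
    already dissolve by depolymerization; ``bonds="all"``: every internal
    bond, with all-C fragments dissolving back into the pool).  On firing, a
    uniformly chosen eligible bond splits the filament; the fragment carrying
    the original C cap keeps the parent's identity, the bare-B fragment
    becomes a new seed with its lineage recorded.  ``k_frag = 0`` reduces
    exactly to :func:`simulate_constant_c`.
    """
    if k_frag < 0:
        raise InvalidParameterError(f"k_frag must be >= 0, got {k_frag}")
    if bonds not in ("bb", "all"):
        raise InvalidParameterError(f"bonds must be 'bb' or 'all', got {bonds!r}")
    if k_frag == 0.0:
        return [simulate_constant_c(rates, conc, t_end, seed_state, rng_seed)]

    rng = np.random.default_rng(rng_seed)
    r = rates
    # per-filament mutable state and histories
    fils = [[seed_state.n_beta, seed_state.cap_k]]
    parents: list[Optional[int]] = [None]
    born = [0.0]
    hist = [([0.0], [seed_state.n_beta], [seed_state.cap_k], [])]
    t = 0.0
    early = False

    def _props(m, k):
        nbonds = (m - 1) if bonds == "bb" else (m + k - 1)
        return (
            r.k_p_cc * conc if k >= 1 else 0.0,
            r.k_p_bc * conc if k == 0 else 0.0,
            r.k_d_cc if k >= 2 else 0.0,
            r.k_d_bc if k == 1 else 0.0,
            r.s_cb if k >= 1 else 0.0,
            r.s_bc if m >= 2 else 0.0,
            r.k_d_bb if (k == 0 and m >= 2) else 0.0,
            k_frag * nbonds,
        )

    fil_props = [_props(*fils[0])]
    fil_tot = [sum(fil_props[0])]
    while True:
        rtot = sum(fil_tot)
        if rtot <= 0:
            early = True
            break
        t_new = t - math.log(rng.random()) / rtot
        if t_new > t_end:
            break
        t = t_new
        u = rng.random() * rtot
        fi = 0
        while u >= fil_tot[fi]:
            u -= fil_tot[fi]
            fi += 1
        code = 0
        for a in fil_props[fi]:
            if u < a:
                break
            u -= a
            code += 1
        m, k = fils[fi]
        if code == 7:
            nbonds = (m - 1) if bonds == "bb" else (m + k - 1)
            j = int(rng.integers(1, nbonds + 1))  # bond between j and j+1
            if j <= m - 1:
                # split inside the beta core: bare-B daughter + cap-keeper
                fils.append([j, 0])
                parents.append(fi)
                born.append(t)
                hist.append(([t], [j], [0], []))
                fil_props.append(_props(j, 0))
                fil_tot.append(sum(fil_props[-1]))
                fils[fi] = [m - j, k]
            else:
                # bonds="all": split inside the cap; the C-only piece dissolves
                ccut = j - (m - 1)  # C monomers retained on the filament
                fils[fi] = [m, ccut - 1]
            times_, nb_, ck_, codes_ = hist[fi]
            times_.append(t)
            nb_.append(fils[fi][0])
            ck_.append(fils[fi][1])
            codes_.append(7)
            fil_props[fi] = _props(*fils[fi])
            fil_tot[fi] = sum(fil_props[fi])
            continue
        if code == 0 or code == 1:
            k += 1
        elif code == 2 or code == 3:
            k -= 1
        elif code == 4:
            k -= 1
            m += 1
        elif code == 5:
            k += 1
            m -= 1
        else:
            m -= 1
        fils[fi] = [m, k]
        fil_props[fi] = _props(m, k)
        fil_tot[fi] = sum(fil_props[fi])
        times_, nb_, ck_, codes_ = hist[fi]
        times_.append(t)
        nb_.append(m)
        ck_.append(k)
        codes_.append(code)

    out = []
    for i, (times_, nb_, ck_, codes_) in enumerate(hist):
        out.append(
            Trajectory(
                times=np.array(times_),
                n_beta=np.array(nb_, dtype=np.int64),
                cap_k=np.array(ck_, dtype=np.int64),
                rng_seed=rng_seed,
                t_end=t_end,
                filament_id=i,
                parent_id=parents[i],
                born=born[i],
                event_codes=np.array(codes_, dtype=np.int8),
                early_stop=early,
                mode="fragmentation",
            )
        )
    return out
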