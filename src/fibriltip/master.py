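"""Brute-force numerical treatment of the truncated cap master equation.

This module exists to validate the closed forms in :mod:`fibriltip.theory` by
a slower, obviously-correct route: build the full transition-rate matrix of
the cap-size chain truncated (reflecting) at ``kmax``, solve its stationary
vector by sparse linear algebra, integrate the forward equation in time, and
measure the mean elongation flux term by term.  Backward switching ``s_bc``
is supported here (it simply adds a second birth channel) even though the
closed forms exclude it.

Performance is a non-goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import csc_matrix, lil_matrix
from scipy.sparse.linalg import expm_multiply, spsolve

from .errors import InvalidParameterError, NonStationaryError, TruncationError
from .model import RateSet

__all__ = [
    "TruncatedChain",
    "build_generator",
    "stationary_distribution",
    "integrate",
    "oracle_velocity",
]

_KMAX_LIMIT = 1 << 14


@dataclass
class TruncatedChain:
    """Cap-size chain truncated at ``kmax`` with generator ``Q`` (columns sum
    to zero; ``dp/dt = Q p``)."""

    kmax: int
    Q: csc_matrix
    rates: RateSet
    conc: float

    @property
    def birth(self) -> np.ndarray:
        return np.array([self.Q[k + 1, k] for k in range(self.kmax)])


def build_generator(rates: RateSet, conc: float, kmax: int) -> TruncatedChain:
    """Assemble the transition-rate matrix of the truncated cap chain.

    Events (cap size k):

    * k -> k+1 at ``k_p_bc*conc + s_bc`` for k = 0 and ``k_p_cc*conc + s_bc``
      for k >= 1 (a backward switch turns the rightmost B into a cap C);
    * k -> k-1 at ``k_d_bc + s_cb`` for k = 1 and ``k_d_cc + s_cb`` for
      k >= 2;
    * reflecting boundary at ``kmax`` (no birth out of the last state), which
      preserves total probability.
    """
    if kmax < 2:
        raise InvalidParameterError(f"kmax must be >= 2, got {kmax}")
    if conc < 0:
        raise InvalidParameterError(f"conc must be >= 0, got {conc}")
    Q = lil_matrix((kmax + 1, kmax + 1))
    for k in range(kmax + 1):
        up = 0.0
        if k < kmax:
            up = (rates.k_p_bc if k == 0 else rates.k_p_cc) * conc + rates.s_bc
            Q[k + 1, k] = up
        down = 0.0
        if k == 1:
            down = rates.k_d_bc + rates.s_cb
        elif k >= 2:
            down = rates.k_d_cc + rates.s_cb
        if k >= 1:
            Q[k - 1, k] = down
        Q[k, k] = -(up + down)
    return TruncatedChain(kmax=kmax, Q=Q.tocsc(), rates=rates, conc=conc)


def _tail_mass(p: np.ndarray, frac: float = 0.05) -> float:
    """Probability mass in the top ``frac`` of states (truncation indicator)."""
    ntail = max(1, int(frac * p.size))
    return float(p[-ntail:].sum())


def stationary_distribution(
    chain: TruncatedChain, tail_tol: float = 1e-10
) -> np.ndarray:
    """Stationary vector of the generator by direct sparse linear solve.

    Solves ``Q p = 0`` with the normalization row appended.  If the solution
    piles probability against the reflecting boundary (tail mass above
    ``tail_tol``) the truncation is too small and a
    :class:`~fibriltip.errors.TruncationError` suggesting a larger ``kmax`` is
    raised — for regime-2 rates no ``kmax`` will ever be large enough.
    """
    n = chain.kmax + 1
    A = chain.Q.tolil(copy=True)
    A[0, :] = 1.0  # replace one redundant balance row by normalization
    b = np.zeros(n)
    b[0] = 1.0
    p = spsolve(A.tocsc(), b)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    if _tail_mass(p) > tail_tol:
        raise TruncationError(
            f"stationary tail mass {_tail_mass(p):.3g} exceeds {tail_tol:g} at "
            f"kmax={chain.kmax}; chain may be non-stationary or under-truncated",
            suggested_kmax=min(2 * chain.kmax, _KMAX_LIMIT),
        )
    return p


def stationary_with_escalation(
    rates: RateSet, conc: float, kmax: int = 64, tail_tol: float = 1e-10
) -> tuple[TruncatedChain, np.ndarray]:
    """Double ``kmax`` until the stationary tail mass is below ``tail_tol``."""
    while True:
        chain = build_generator(rates, conc, kmax)
        try:
            return chain, stationary_distribution(chain, tail_tol)
        except TruncationError:
            if kmax >= _KMAX_LIMIT:
                raise
            kmax = min(2 * kmax, _KMAX_LIMIT)


@dataclass
class IntegrationResult:
    """Time-indexed probability vectors from forward integration."""

    times: np.ndarray
    p_t: np.ndarray  # shape (ntimes, kmax+1)
    converged: bool  # steady state reached by the last output time


def integrate(
    chain: TruncatedChain,
    p0: np.ndarray,
    t_end: float,
    dt_out: float,
    steady_tol: float = 1e-10,
) -> IntegrationResult:
    """Integrate ``dp/dt = Q p`` by the (stiff-safe) matrix exponential.

    Probability is conserved to 1e-8 at every output time; the steady-state
    flag raises when ``||Q p||_inf`` drops below ``steady_tol``.  For regime-2
    rates probability drifts toward the reflecting boundary and the flag never
    raises within ``t_end`` (a partial result is still returned).
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (chain.kmax + 1,) or abs(p0.sum() - 1.0) > 1e-9 or (p0 < 0).any():
        raise InvalidParameterError("p0 must be a probability vector over 0..kmax")
    nsteps = max(1, int(round(t_end / dt_out)))
    times = np.linspace(0.0, nsteps * dt_out, nsteps + 1)
    p_t = np.empty((nsteps + 1, chain.kmax + 1))
    p_t[0] = p0
    p = p0
    for i in range(1, nsteps + 1):
        p = expm_multiply(chain.Q * dt_out, p)
        p = np.clip(p, 0.0, None)
        if abs(p.sum() - 1.0) > 1e-8:  # pragma: no cover - conservation guard
            raise AssertionError(f"probability lost at t={times[i]}: sum={p.sum()}")
        p /= p.sum()
        p_t[i] = p
    converged = float(np.abs(chain.Q @ p).max()) < steady_tol
    return IntegrationResult(times=times, p_t=p_t, converged=converged)


def oracle_velocity(
    chain: TruncatedChain,
    p_stationary: Optional[np.ndarray] = None,
    tail_tol: float = 1e-10,
) -> float:
    """Mean elongation flux under the stationary cap distribution.

    Sums ``p_k * (gain_k - loss_k)`` with the boundary special cases: gain at
    k = 0 is B-end binding, loss at k = 1 is unbinding from the B end;
    switching moves no length and is excluded.  Raises
    :class:`~fibriltip.errors.NonStationaryError` for regime-2 input.
    """
    if p_stationary is None:
        try:
            p_stationary = stationary_distribution(chain, tail_tol)
        except TruncationError as e:
            raise NonStationaryError(
                "no stationary cap distribution (regime 2 or under-truncated): "
                f"{e}"
            ) from e
    r = chain.rates
    c = chain.conc
    k = np.arange(chain.kmax + 1)
    gain = np.where(k == 0, r.k_p_bc * c, r.k_p_cc * c)
    gain[-1] = 0.0  # reflecting boundary: no growth out of kmax
    loss = np.where(k == 1, r.k_d_bc, np.where(k >= 2, r.k_d_cc, 0.0))
    return float(np.dot(p_stationary, gain - loss))
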