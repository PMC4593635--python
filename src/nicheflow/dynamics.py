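"""Yodzis-Innes bioenergetic dynamics on a parametrized food web.

State variables are total energy contents B_i.  Producers grow logistically,
consumers pay a metabolic cost x_i * B_i, and predation follows a Holling
type III functional response with predator interference:

    F_ij(B) = B_j^(1+q) / (B0^(1+q) + c * B_i * B0^(1+q) + sum_{k in prey(i)} B_k^(1+q))

The assimilated gain of consumer i from prey j is x_i * y * B_i * F_ij; the
prey loses the pre-assimilation amount, i.e. the gain divided by the
conversion efficiency e_ij (0.45 when j is a producer, 0.85 otherwise).

Integration uses classic fixed-step fourth-order Runge-Kutta; the
simulation protocol runs two phases of equal length, removing species whose
biomass has fallen below an extinction threshold between phases, and only
the second (post-transient) phase is analyzed downstream.

The inner RK4 loop is JIT-compiled (numba) over a CSR encoding of the prey
lists; :func:`biomass_derivative` is an independent vectorized reference
implementation used for testing and for building flow snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .nichemodel import count_components
from .trophic import ParametrizedWeb

__all__ = [
    "SimulationResult",
    "functional_response",
    "functional_response_matrix",
    "biomass_derivative",
    "integrate",
    "run_protocol",
    "EXTINCTION_THRESHOLD",
]

EXTINCTION_THRESHOLD = 1e-6


@dataclass
class SimulationResult:
    """Outcome of the two-phase simulation protocol.

    ``trajectory`` holds phase-2 biomasses at integer model times 0..T
    (rows), for the surviving species only.  ``extinct_ids`` are indices
    into the *original* web.  ``degenerate`` flags runs that cannot be
    analyzed (all species or all producers extinct, or the surviving web
    disconnected); ``failed`` flags numerical blow-up (non-finite state).
    """

    surviving_web: ParametrizedWeb | None
    trajectory: np.ndarray  # (T+1, S_surv)
    times: np.ndarray
    surviving_ids: np.ndarray
    extinct_ids: np.ndarray
    steady_state_gap: float
    degenerate: bool = False
    failed: bool = False
    B_initial: np.ndarray | None = None


def functional_response_matrix(B: np.ndarray, pweb: ParametrizedWeb) -> np.ndarray:
    """Matrix F with F[i, j] = fraction of max consumption of prey j by i.

    Rows of consumers with no (or all-zero) prey are zero by convention.
    """
    B = np.asarray(B, dtype=float)
    A = pweb.A
    qp1 = 1.0 + pweb.q
    Bq = B**qp1
    prey_sum = A @ Bq
    denom = pweb.B0**qp1 * (1.0 + pweb.c * B) + prey_sum
    F = (A * Bq[None, :]) / denom[:, None]
    # rows with zero prey biomass: numerator already zero, denom > 0
    return F


def functional_response(B: np.ndarray, pweb: ParametrizedWeb, i: int, j: int) -> float:
    """F_ij(B) for a single consumer-prey pair."""
    if not pweb.A[i, j]:
        raise ValueError(f"species {i} does not consume species {j}")
    return float(functional_response_matrix(B, pweb)[i, j])


def assimilated_flow_matrix(B: np.ndarray, pweb: ParametrizedWeb) -> np.ndarray:
    """f[i, j] = x_i * y * B_i * F_ij, the assimilated flow from j to i."""
    F = functional_response_matrix(B, pweb)
    return (pweb.x * pweb.y * np.asarray(B, dtype=float))[:, None] * F


def biomass_derivative(B: np.ndarray, pweb: ParametrizedWeb) -> np.ndarray:
    """dB/dt for every species (vectorized reference implementation)."""
    B = np.asarray(B, dtype=float)
    if not np.isfinite(B).all():
        raise FloatingPointError("non-finite biomass passed to biomass_derivative")
    f = assimilated_flow_matrix(B, pweb)
    gains = f.sum(axis=1)
    predation_losses = (f / pweb.e_col[None, :]).sum(axis=0)
    growth = np.where(pweb.is_producer, pweb.r * B * (1.0 - B / pweb.K), -pweb.x * B)
    consumer_gain = np.where(pweb.is_producer, 0.0, gains)
    return growth + consumer_gain - predation_losses


@njit(cache=True, fastmath=False)
def _rhs(B, Bq, indptr, indices, x, inv_e_col, rK_growth_r, K, is_prod, y, q, c, B0, out):  # pragma: no cover
    S = B.shape[0]
    qp1 = 1.0 + q
    if qp1 == 2.0:
        for s in range(S):
            Bq[s] = B[s] * B[s]
    else:
        for s in range(S):
            Bq[s] = B[s] ** qp1
    for j in range(S):
        if is_prod[j]:
            out[j] = rK_growth_r[j] * B[j] * (1.0 - B[j] / K[j])
        else:
            out[j] = -x[j] * B[j]
    B0q = B0**qp1
    for i in range(S):
        lo, hi = indptr[i], indptr[i + 1]
        if lo == hi:
            continue
        denom = B0q * (1.0 + c * B[i])
        for p in range(lo, hi):
            denom += Bq[indices[p]]
        coef = x[i] * y * B[i] / denom
        for p in range(lo, hi):
            jj = indices[p]
            gain = coef * Bq[jj]
            out[i] += gain
            out[jj] -= gain * inv_e_col[jj]
    return out


@njit(cache=True)
def _integrate_rk4(B0vec, indptr, indices, x, e_col, r, K, is_prod, y, q, c, B0,
                   duration, steps_per_unit):  # pragma: no cover
    """Fixed-step RK4 recording states at integer model times.

    Returns (states, ok_flag, fail_time).  On non-finite state the
    trajectory is truncated (remaining rows NaN) and ok_flag is False.
    """
    S = B0vec.shape[0]
    dt = 1.0 / steps_per_unit
    states = np.full((duration + 1, S), np.nan)
    states[0] = B0vec
    B = B0vec.copy()
    inv_e = 1.0 / e_col
    k1 = np.empty(S)
    k2 = np.empty(S)
    k3 = np.empty(S)
    k4 = np.empty(S)
    tmp = np.empty(S)
    bq = np.empty(S)
    for unit in range(duration):
        for _ in range(steps_per_unit):
            _rhs(B, bq, indptr, indices, x, inv_e, r, K, is_prod, y, q, c, B0, k1)
            for s in range(S):
                tmp[s] = B[s] + 0.5 * dt * k1[s]
            _rhs(tmp, bq, indptr, indices, x, inv_e, r, K, is_prod, y, q, c, B0, k2)
            for s in range(S):
                tmp[s] = B[s] + 0.5 * dt * k2[s]
            _rhs(tmp, bq, indptr, indices, x, inv_e, r, K, is_prod, y, q, c, B0, k3)
            for s in range(S):
                tmp[s] = B[s] + dt * k3[s]
            _rhs(tmp, bq, indptr, indices, x, inv_e, r, K, is_prod, y, q, c, B0, k4)
            for s in range(S):
                B[s] += dt / 6.0 * (k1[s] + 2.0 * k2[s] + 2.0 * k3[s] + k4[s])
        if not np.isfinite(B).all():
            return states, False, float(unit + 1)
        states[unit + 1] = B
    return states, True, -1.0


def _prey_csr(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CSR encoding (indptr, indices) of each consumer's prey list."""
    A = np.asarray(A)
    indptr = np.zeros(A.shape[0] + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(A.sum(axis=1))
    indices = np.flatnonzero(A.ravel()) % A.shape[1]
    return indptr, indices.astype(np.int64)


class IntegrationFailure(RuntimeError):
    """Non-finite state encountered during integration."""

    def __init__(self, time: float, states: np.ndarray):
        super().__init__(f"non-finite biomass at model time {time}")
        self.time = time
        self.states = states


def integrate(
    pweb: ParametrizedWeb,
    B_init: np.ndarray,
    duration: int,
    dt: float = 0.01,
) -> np.ndarray:
    """Integrate the web for ``duration`` model time units with RK4.

    Returns an array of shape (duration + 1, S): the biomass state at every
    integer model time, including t = 0.  ``dt`` must divide 1 evenly.
    Raises :class:`IntegrationFailure` if the state becomes non-finite.
    """
    steps_per_unit = round(1.0 / dt)
    if abs(steps_per_unit * dt - 1.0) > 1e-12:
        raise ValueError(f"dt={dt} does not evenly divide one time unit")
    if duration < 0:
        raise ValueError("duration must be a nonnegative integer")
    B_init = np.asarray(B_init, dtype=float)
    indptr, indices = _prey_csr(pweb.A)
    states, ok, fail_time = _integrate_rk4(
        B_init, indptr, indices,
        pweb.x.astype(float), pweb.e_col.astype(float),
        pweb.r.astype(float), pweb.K.astype(float),
        pweb.is_producer.astype(np.bool_),
        float(pweb.y), float(pweb.q), float(pweb.c), float(pweb.B0),
        int(duration), steps_per_unit,
    )
    if not ok:
        raise IntegrationFailure(fail_time, states)
    return states


def run_protocol(
    pweb: ParametrizedWeb,
    rng: np.random.Generator,
    duration_phase1: int = 1000,
    duration_phase2: int = 1000,
    dt: float = 0.01,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> SimulationResult:
    """Two-phase simulation: burn-in, single extinction pass, analysis phase.

    Initial biomasses are drawn from Uniform(0.5, 1).  After phase 1, every
    species with biomass below ``extinction_threshold`` is removed (its rows
    and columns sliced out of the adjacency and parameter vectors) and the
    reduced web is integrated for phase 2, whose integer-time trajectory is
    returned.
    """
    S = pweb.S
    B0_init = rng.uniform(0.5, 1.0, size=S)
    empty = np.empty((0, 0))
    try:
        phase1 = integrate(pweb, B0_init, duration_phase1, dt=dt)
    except IntegrationFailure:
        return SimulationResult(
            surviving_web=None, trajectory=empty, times=np.empty(0),
            surviving_ids=np.empty(0, dtype=int), extinct_ids=np.arange(S),
            steady_state_gap=np.nan, degenerate=True, failed=True,
            B_initial=B0_init,
        )
    B_end = phase1[-1]
    alive = B_end >= extinction_threshold
    surviving_ids = np.flatnonzero(alive)
    extinct_ids = np.flatnonzero(~alive)

    degenerate = False
    if surviving_ids.size == 0:
        degenerate = True
    else:
        sub = pweb.subset(surviving_ids)
        if not sub.is_producer.any():
            degenerate = True
        elif sub.S > 1 and count_components(sub.A) > count_components(pweb.A):
            # extinctions split the web into more pieces than it started with
            degenerate = True
    if degenerate:
        return SimulationResult(
            surviving_web=None, trajectory=empty, times=np.empty(0),
            surviving_ids=surviving_ids, extinct_ids=extinct_ids,
            steady_state_gap=np.nan, degenerate=True, B_initial=B0_init,
        )

    try:
        phase2 = integrate(sub, B_end[alive], duration_phase2, dt=dt)
    except IntegrationFailure:
        return SimulationResult(
            surviving_web=sub, trajectory=empty, times=np.empty(0),
            surviving_ids=surviving_ids, extinct_ids=extinct_ids,
            steady_state_gap=np.nan, degenerate=True, failed=True,
            B_initial=B0_init,
        )
    gap = float(np.max(np.abs(biomass_derivative(phase2[-1], sub)))) if sub.S else np.nan
    return SimulationResult(
        surviving_web=sub,
        trajectory=phase2,
        times=np.arange(duration_phase2 + 1, dtype=float),
        surviving_ids=surviving_ids,
        extinct_ids=extinct_ids,
        steady_state_gap=gap,
        B_initial=B0_init,
    )
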