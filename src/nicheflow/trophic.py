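"""Trophic levels and Yodzis-Innes parametrization.

The trophic level of each species is the mean of two purely topological
quantities: (1) one plus the shortest directed path (consumer -> prey hops)
to any basal species, and (2) the flow-based trophic position
TL_i = 1 + sum_j TL_j * p_ji under the equal-diet-fractions assumption
(p_ji = 1/|prey(i)| for each prey j of i).  Producers are level 1 under
both.  Body mass then follows the empirical mass-trophic-level relation
m = 10**(TL - 1), and mass-specific metabolic rates follow quarter-power
scaling: x = 0.138 for producers, 0.314 * m**(-1/4) for consumers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nichemodel import TopologicalWeb

__all__ = [
    "ParametrizedWeb",
    "TrophicError",
    "flow_trophic_position",
    "distance_trophic_level",
    "parametrize",
]

# Yodzis-Innes parameter constants (dimensionless / normalized units)
METABOLIC_PRODUCER = 0.138
METABOLIC_COEF = 0.314
METABOLIC_EXP = -0.25
MAX_CONSUMPTION = 8.0  # y_ij
EFF_ON_PRODUCER = 0.45  # e_ij when prey j is a producer
EFF_ON_CONSUMER = 0.85
REWARD_SENSITIVITY = 1.0  # q
INTERFERENCE = 1.0  # c
HALF_SATURATION = 0.5  # B0


class TrophicError(ValueError):
    """Trophic levels cannot be assigned (no basal access)."""


@dataclass
class ParametrizedWeb:
    """A topological web plus trophic levels and all dynamical parameters.

    Parameter vectors are indexed by species; ``e_col[j]`` is the conversion
    efficiency of any consumer feeding on prey j (it depends only on whether
    j is a producer).  ``q``, ``c``, ``B0`` and ``y`` are shared scalars.
    """

    web: TopologicalWeb
    TL: np.ndarray
    TL_flow: np.ndarray
    TL_distance: np.ndarray
    is_producer: np.ndarray  # bool
    m: np.ndarray  # body mass
    x: np.ndarray  # mass-specific metabolic rate
    r: np.ndarray  # intrinsic growth rate (1 producers, 0 otherwise)
    K: np.ndarray  # carrying capacity
    e_col: np.ndarray  # conversion efficiency by prey species
    y: float = MAX_CONSUMPTION
    q: float = REWARD_SENSITIVITY
    c: float = INTERFERENCE
    B0: float = HALF_SATURATION

    @property
    def S(self) -> int:
        return self.web.S

    @property
    def A(self) -> np.ndarray:
        return self.web.A

    def subset(self, keep: np.ndarray) -> "ParametrizedWeb":
        """Restrict the web to the species in ``keep`` (bool mask or index).

        Parameters assigned at parametrization time (trophic level, mass,
        rates) are carried over unchanged, as they describe the species, not
        the reduced topology.
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        sub = TopologicalWeb(
            S=keep.size,
            C_target=self.web.C_target,
            n=self.web.n[keep],
            r=self.web.r[keep],
            c=self.web.c[keep],
            A=self.web.A[np.ix_(keep, keep)],
        )
        return ParametrizedWeb(
            web=sub,
            TL=self.TL[keep],
            TL_flow=self.TL_flow[keep],
            TL_distance=self.TL_distance[keep],
            is_producer=self.is_producer[keep],
            m=self.m[keep],
            x=self.x[keep],
            r=self.r[keep],
            K=self.K[keep],
            e_col=self.e_col[keep],
            y=self.y,
            q=self.q,
            c=self.c,
            B0=self.B0,
        )


def flow_trophic_position(A: np.ndarray) -> np.ndarray:
    """Flow-based trophic position under equal diet fractions.

    Solves TL = 1 + D @ TL where D[i, j] = A[i, j] / |prey(i)| (zero rows
    for producers).  Cannibalistic self-links are excluded from the diet:
    they make the system singular (a pure self-feeder would need
    TL = 1 + TL) and carry no information about trophic height.  A species
    whose only prey is itself is therefore assigned level 1.
    """
    A = np.asarray(A, dtype=float)
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    S = A.shape[0]
    prey_counts = A.sum(axis=1)
    D = np.divide(A, prey_counts[:, None], out=np.zeros_like(A), where=prey_counts[:, None] > 0)
    M = np.eye(S) - D
    try:
        TL = np.linalg.solve(M, np.ones(S))
    except np.linalg.LinAlgError as exc:
        bad = _species_without_basal_access(A)
        raise TrophicError(
            f"flow trophic positions undefined; species without basal access: {bad}"
        ) from exc
    resid = np.max(np.abs(M @ TL - 1.0))
    if not np.isfinite(TL).all() or resid > 1e-10:
        bad = _species_without_basal_access(A)
        raise TrophicError(
            f"flow trophic system singular or ill-conditioned "
            f"(residual {resid:.3g}); species without basal access: {bad}"
        )
    return TL


def _species_without_basal_access(A: np.ndarray) -> list[int]:
    dist = _distance_to_basal(A)
    return [int(i) for i in np.flatnonzero(~np.isfinite(dist))]


def _distance_to_basal(A: np.ndarray) -> np.ndarray:
    """Shortest consumer->prey hop count to a basal species (0 for basal).

    Self-links are ignored: they can neither shorten a path nor make a
    species non-basal for trophic purposes.
    """
    A = (np.asarray(A) != 0).copy()
    np.fill_diagonal(A, False)
    S = A.shape[0]
    prey_counts = A.sum(axis=1)
    dist = np.full(S, np.inf)
    frontier = prey_counts == 0
    dist[frontier] = 0.0
    d = 0
    while frontier.any():
        d += 1
        # consumers with at least one prey in the current frontier
        reaches = (A[:, frontier].any(axis=1)) & ~np.isfinite(dist)
        if not reaches.any():
            break
        dist[reaches] = d
        frontier = reaches
    return dist


def distance_trophic_level(A: np.ndarray) -> np.ndarray:
    """1 + shortest directed path length to the nearest basal species."""
    dist = _distance_to_basal(A)
    if not np.isfinite(dist).all():
        bad = [int(i) for i in np.flatnonzero(~np.isfinite(dist))]
        raise TrophicError(f"species with no directed path to a producer: {bad}")
    return dist + 1.0


def parametrize(web: TopologicalWeb) -> ParametrizedWeb:
    """Assign trophic levels, body masses and all Yodzis-Innes parameters."""
    A = web.A
    tl_flow = flow_trophic_position(A)
    tl_dist = distance_trophic_level(A)
    TL = 0.5 * (tl_flow + tl_dist)
    is_producer = A.sum(axis=1) == 0
    m = 10.0 ** (TL - 1.0)
    x = np.where(is_producer, METABOLIC_PRODUCER, METABOLIC_COEF * m**METABOLIC_EXP)
    r = np.where(is_producer, 1.0, 0.0)
    K = np.ones(web.S)
    e_col = np.where(is_producer, EFF_ON_PRODUCER, EFF_ON_CONSUMER)
    return ParametrizedWeb(
        web=web,
        TL=TL,
        TL_flow=tl_flow,
        TL_distance=tl_dist,
        is_producer=is_producer,
        m=m,
        x=x,
        r=r,
        K=K,
        e_col=e_col,
    )
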