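"""Dynamic environ approximation (DEA) and flow indirectness.

Environ analysis requires a conservative stock-and-flow description, which
the bioenergetic model does not supply directly: predators assimilate less
energy than prey lose.  The snapshot bookkeeping therefore treats producer
net growth as the system's boundary input, and unassimilated food plus
metabolic losses as boundary outputs, so that every compartment balances:

    dB_j/dt = z_j + sum_k f[j, k] - t_out_j

with f[i, j] the assimilated internal flow from prey j to consumer i,
z_j the boundary input and t_out_j the total outflow of j.

Each snapshot is normalized to a nondimensional flow-intensity matrix G
(g_ij = f_ij / t_out_j, diagonal forced to zero).  Over a window of m
integer time steps the integral-flow matrix is the time-ordered product
series

    N(t0) = I + G(t0) + G(t0) G(t0+1) + ... + G(t0) ... G(t0+m-1)

and flow indirectness of each link is FI_ij = (N_ij - G_ij(t0)) / N_ij:
the fraction of prey-to-predator flow that traveled over paths of length
greater than one.  Web-level FI is the mean over realized predator-prey
links.  Negative flows (numerical failure) make FI leave [0, 1]; such runs
carry valid=False and are excluded from aggregate statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SimulationResult, assimilated_flow_matrix, biomass_derivative
from .trophic import ParametrizedWeb

__all__ = [
    "FlowSnapshot",
    "DEAResult",
    "flow_snapshot",
    "normalized_flow_matrix",
    "integral_flow",
    "flow_indirectness",
    "run_dea",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 20


@dataclass
class FlowSnapshot:
    """Conservative flow state of the web at one instant.

    ``f[i, j]`` is the assimilated internal flow from j to i; ``z`` boundary
    inputs (producer net growth); ``o`` boundary outputs (metabolic losses,
    unassimilated food, and any negative net growth magnitude); ``t_out``
    total outflow per species, equal to ``o + f.sum(axis=0)``.
    """

    f: np.ndarray
    z: np.ndarray
    o: np.ndarray
    t_out: np.ndarray
    valid: bool = True


@dataclass
class DEAResult:
    """DEA output for one run.

    ``mean_FI``/``FI``/``valid`` follow the configured FI definition
    (ratio by default); the web-level mean under the other definition is
    always recorded alongside for sensitivity analysis.
    """

    G_series: list[np.ndarray]
    window: int
    N: np.ndarray | None
    FI: np.ndarray | None
    mean_FI: float
    valid: bool
    degenerate: bool = False
    mean_FI_ratio: float = np.nan
    mean_FI_difference: float = np.nan
    valid_ratio: bool = False
    valid_difference: bool = False


def flow_snapshot(
    B: np.ndarray,
    pweb: ParametrizedWeb,
    producer_respiration: bool = True,
) -> FlowSnapshot:
    """Build the conservative flow matrix and boundary flows at state B.

    With ``producer_respiration`` (default), producers pay a metabolic
    boundary output x_j * B_j balanced by a gross-production input
    z_j = r_j * B_j * (1 - B_j / K_j) + x_j * B_j, so every compartment's
    throughflow includes its respiration; with it off, the logistic term is
    taken as the (net) boundary input and producers respire nothing.  Node
    balance dB_j/dt = z_j + inflows_j - t_out_j holds either way.
    """
    B = np.asarray(B, dtype=float)
    f = assimilated_flow_matrix(B, pweb)
    pre_assim = f / pweb.e_col[None, :]  # what prey j actually loses
    predation_out = pre_assim.sum(axis=0)
    unassimilated = predation_out - f.sum(axis=0)

    net_growth = np.where(pweb.is_producer, pweb.r * B * (1.0 - B / pweb.K), 0.0)
    if producer_respiration:
        respiration = pweb.x * B  # all species
        z = np.maximum(net_growth, 0.0) + np.where(pweb.is_producer, respiration, 0.0)
    else:
        respiration = np.where(pweb.is_producer, 0.0, pweb.x * B)
        z = np.maximum(net_growth, 0.0)
    o = respiration + unassimilated + np.maximum(-net_growth, 0.0)
    t_out = o + f.sum(axis=0)
    valid = bool(np.isfinite(B).all() and (B >= 0).all() and (f >= 0).all())
    return FlowSnapshot(f=f, z=z, o=o, t_out=t_out, valid=valid)


def normalized_flow_matrix(snap: FlowSnapshot) -> np.ndarray:
    """Nondimensional flow intensities g_ij = f_ij / t_out_j, g_ii = 0.

    A cannibal's self-flow stays in its t_out but is excluded from G.
    Columns with zero total outflow must carry no flow.
    """
    f = snap.f
    t_out = snap.t_out
    zero = t_out <= 0
    if np.any(zero & (f.sum(axis=0) > 0)):
        raise ValueError("species with zero total outflow but nonzero outgoing flow")
    safe = np.where(zero, 1.0, t_out)
    G = f / safe[None, :]
    np.fill_diagonal(G, 0.0)
    return G


def integral_flow(G_series: list[np.ndarray] | np.ndarray, m: int) -> np.ndarray:
    """Windowed integral-flow matrix N from a sequence of G matrices.

    N = I + sum_{k=1..m} G(t0) G(t0+1) ... G(t0+k-1); requires at least m
    matrices from t0 onward.  With a constant G this is the truncated
    Neumann series sum_{k=0..m} G^k.
    """
    G_series = [np.asarray(G, dtype=float) for G in G_series]
    if m < 0:
        raise ValueError("window must be nonnegative")
    if len(G_series) < m:
        raise ValueError(f"need at least {m} G matrices for window {m}, got {len(G_series)}")
    S = G_series[0].shape[0]
    N = np.eye(S)
    prod = np.eye(S)
    for k in range(m):
        prod = prod @ G_series[k]
        N += prod
    return N


def flow_indirectness(
    N: np.ndarray,
    G_t0: np.ndarray,
    A: np.ndarray,
    definition: str = "ratio",
) -> tuple[np.ndarray, float, bool]:
    """FI matrix, link-averaged mean FI and validity flag.

    ``definition="ratio"`` (default): FI_ij = (N_ij - G_ij) / N_ij where
    N_ij > 0, 0 elsewhere — the fraction of integral flow on the link that
    traveled over paths of length > 1.  ``definition="difference"``:
    FI_ij = N_ij - G_ij, the absolute indirect flow intensity.  Under both,
    the diagonal (self-cycles) is forced to 0 and mean_FI averages FI over
    ordered pairs (i, j) with a realized link A[i, j] = 1, i != j and
    N_ij > 0.  valid is False when any off-diagonal FI falls outside
    [0, 1] — automatic for the ratio with nonnegative flows, a substantive
    exclusion rule for the difference (strong cycling can push N - G
    above 1).
    """
    N = np.asarray(N, dtype=float)
    G_t0 = np.asarray(G_t0, dtype=float)
    pos = N > 0
    if definition == "ratio":
        FI = np.zeros_like(N)
        FI[pos] = (N[pos] - G_t0[pos]) / N[pos]
    elif definition == "difference":
        FI = N - G_t0
    else:
        raise ValueError(f"unknown FI definition {definition!r}")
    np.fill_diagonal(FI, 0.0)
    offdiag = ~np.eye(N.shape[0], dtype=bool)
    valid = bool((FI[offdiag] >= 0.0).all() and (FI[offdiag] <= 1.0).all())

    links = (np.asarray(A) != 0) & offdiag & pos
    if not links.any():
        return FI, np.nan, False
    return FI, float(FI[links].mean()), valid


def run_dea(
    sim: SimulationResult,
    window: int = DEFAULT_WINDOW,
    producer_respiration: bool = True,
    definition: str = "ratio",
) -> DEAResult:
    """DEA over the final ``window`` time steps of the phase-2 trajectory.

    G matrices are built at the last window+1 integer times; N is computed
    once at the single starting time t0 = T - window, where the run is
    closest to steady state.
    """
    if sim.degenerate or sim.surviving_web is None:
        return DEAResult(G_series=[], window=window, N=None, FI=None,
                         mean_FI=np.nan, valid=False, degenerate=True)
    traj = sim.trajectory
    if traj.shape[0] < window + 1:
        raise ValueError(
            f"trajectory has {traj.shape[0]} integer times; window {window} needs {window + 1}"
        )
    pweb = sim.surviving_web
    snaps = [
        flow_snapshot(traj[t], pweb, producer_respiration=producer_respiration)
        for t in range(traj.shape[0] - window - 1, traj.shape[0])
    ]
    snaps_valid = all(s.valid for s in snaps)
    try:
        G_series = [normalized_flow_matrix(s) for s in snaps]
    except ValueError:
        return DEAResult(G_series=[], window=window, N=None, FI=None,
                         mean_FI=np.nan, valid=False, degenerate=True)
    N = integral_flow(G_series, window)
    FI_r, mfi_r, ok_r = flow_indirectness(N, G_series[0], pweb.A, "ratio")
    FI_d, mfi_d, ok_d = flow_indirectness(N, G_series[0], pweb.A, "difference")
    FI, mean_FI, fi_valid = (FI_r, mfi_r, ok_r) if definition == "ratio" else (FI_d, mfi_d, ok_d)
    if np.isnan(mean_FI):
        return DEAResult(G_series=G_series, window=window, N=N, FI=FI,
                         mean_FI=np.nan, valid=False, degenerate=True)
    return DEAResult(
        G_series=G_series, window=window, N=N, FI=FI,
        mean_FI=mean_FI, valid=snaps_valid and fi_valid,
        mean_FI_ratio=mfi_r, mean_FI_difference=mfi_d,
        valid_ratio=snaps_valid and ok_r, valid_difference=snaps_valid and ok_d,
    )
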