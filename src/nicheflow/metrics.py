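"""Topological and ecological predictor metrics for food webs.

The suite covers the five predictors that dominate the regression-tree
analysis (mean path length, dominant eigenvalue of the adjacency matrix,
actual connectance, mean trophic level, fraction of intermediate species)
plus a documented set of standard food-web descriptors, about 27 named
scalars in total.

Conventions:
- PathLen defaults to the undirected characteristic path length (mean
  shortest-path distance over unordered pairs of distinct species,
  self-loops ignored); a directed reachable-pairs mode is available.
- DomEig is the spectral radius of the directed adjacency with self-loops
  retained (cannibalism is a one-cycle); it is zero iff the web is acyclic.
- A species is basal if it has no prey, top if it has no predators,
  intermediate if it has both; self-links are excluded from those counts.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .trophic import ParametrizedWeb

__all__ = [
    "mean_path_length",
    "dominant_eigenvalue",
    "compute_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = [
    "Size", "ConAct", "LinkDensity", "PathLen", "PathLenDirected", "DomEig",
    "MeanTroph", "SDTroph", "MaxTroph", "TrophInter", "TrophBasal", "TrophTop",
    "FracCannibal", "FracOmnivore", "FracHerbivore", "MeanGenerality",
    "SDGenerality", "MeanVulnerability", "SDVulnerability", "SDGenNorm",
    "SDVulNorm", "Clustering", "MeanDegree", "SDDegree", "Diameter",
    "NumLinks", "LoopFrac",
]


def _undirected_graph(A: np.ndarray) -> nx.Graph:
    A = np.asarray(A) != 0
    und = A | A.T
    np.fill_diagonal(und, False)
    return nx.from_numpy_array(und.astype(int))


def mean_path_length(A: np.ndarray, directed: bool = False) -> float:
    """Characteristic path length of the web.

    Default mode: mean undirected shortest-path distance over all unordered
    pairs of distinct species (self-loops ignored); raises on disconnected
    webs.  ``directed=True`` averages directed distances over reachable
    ordered pairs instead.
    """
    A = np.asarray(A)
    S = A.shape[0]
    if S < 2:
        return 0.0
    if directed:
        Ad = (A != 0).astype(int)
        np.fill_diagonal(Ad, 0)
        g = nx.from_numpy_array(Ad, create_using=nx.DiGraph)
        total, npairs = 0, 0
        for src, dists in nx.all_pairs_shortest_path_length(g):
            for dst, d in dists.items():
                if dst != src:
                    total += d
                    npairs += 1
        return total / npairs if npairs else np.nan
    g = _undirected_graph(A)
    if not nx.is_connected(g):
        raise ValueError("mean path length undefined: web is not connected")
    return nx.average_shortest_path_length(g)


def dominant_eigenvalue(A: np.ndarray) -> float:
    """Spectral radius of the directed adjacency (self-loops retained)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if A.size == 0:
        return 0.0
    eig = np.linalg.eigvals(A)
    rho = float(np.max(np.abs(eig)))
    # acyclic webs are nilpotent: spectral radius exactly 0 up to roundoff
    return 0.0 if rho < 1e-9 * A.shape[0] else rho


def compute_metrics(pweb: ParametrizedWeb) -> dict[str, float]:
    """All predictor metrics for a (parametrized) web, as a flat dict."""
    A = np.asarray(pweb.A) != 0
    S = A.shape[0]
    L = int(A.sum())
    Anl = A.copy()
    np.fill_diagonal(Anl, False)  # self-links excluded from role counts

    n_prey = Anl.sum(axis=1)  # generality, self-links excluded
    n_pred = Anl.sum(axis=0)  # vulnerability
    basal = n_prey == 0
    top = (n_pred == 0) & ~basal
    inter = (n_prey > 0) & (n_pred > 0)
    cannibal = np.diag(A)
    # omnivore: consumer feeding at more than one (distance) trophic level
    omn = np.zeros(S, dtype=bool)
    for i in range(S):
        prey = np.flatnonzero(Anl[i])
        if prey.size > 1:
            omn[i] = len(np.unique(np.round(pweb.TL_distance[prey], 9))) > 1
    herb = np.array([
        bool(n_prey[i] > 0 and basal[np.flatnonzero(Anl[i])].all()) for i in range(S)
    ])

    consumers = n_prey > 0
    gen = n_prey[consumers] if consumers.any() else np.array([0.0])
    preyed = n_pred > 0
    vul = n_pred[preyed] if preyed.any() else np.array([0.0])
    link_density = L / S
    degree = n_prey + n_pred

    tl = pweb.TL
    und = _undirected_graph(A)
    path_len = mean_path_length(A) if L > 0 else 0.0

    return {
        "Size": float(S),
        "ConAct": L / S**2,
        "LinkDensity": link_density,
        "PathLen": path_len,
        "PathLenDirected": mean_path_length(A, directed=True) if L > 0 else 0.0,
        "DomEig": dominant_eigenvalue(A.astype(float)),
        "MeanTroph": float(tl.mean()),
        "SDTroph": float(tl.std()),
        "MaxTroph": float(tl.max()),
        "TrophInter": float(inter.mean()),
        "TrophBasal": float(basal.mean()),
        "TrophTop": float(top.mean()),
        "FracCannibal": float(cannibal.mean()),
        "FracOmnivore": float(omn.mean()),
        "FracHerbivore": float(herb.mean()),
        "MeanGenerality": float(gen.mean()),
        "SDGenerality": float(gen.std()),
        "MeanVulnerability": float(vul.mean()),
        "SDVulnerability": float(vul.std()),
        "SDGenNorm": float(gen.std() / link_density) if link_density > 0 else 0.0,
        "SDVulNorm": float(vul.std() / link_density) if link_density > 0 else 0.0,
        "Clustering": float(nx.average_clustering(und)),
        "MeanDegree": float(degree.mean()),
        "SDDegree": float(degree.std()),
        "Diameter": float(nx.diameter(und)) if S > 1 and nx.is_connected(und) else 0.0,
        "NumLinks": float(L),
        "LoopFrac": float(np.trace(A.astype(int)) / L) if L > 0 else 0.0,
    }
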