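"""Stochastic niche-model food-web topology generation.

Species are placed on a one-dimensional niche axis: each species i gets a
niche value n_i ~ Uniform(0, 1), a feeding-range width r_i = n_i * b_i with
b_i ~ Beta(1, (1 - 2C) / (2C)) so that E[r] = C, and a range center
c_i ~ Uniform(r_i / 2, n_i).  Species i consumes every species (possibly
itself) whose niche value falls inside [c_i - r_i/2, c_i + r_i/2].

Connectance is defined as C = L / S**2, the fraction of possible directed
links that are realized.  Candidate webs are rejection-sampled until they
have at least one producer (a species with no prey) and form a single
connected component; the component count is obtained as the multiplicity of
the zero eigenvalue of the graph Laplacian of the undirected, self-loop-free
adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TopologicalWeb",
    "NicheModelError",
    "WebGenerationError",
    "beta_shape",
    "draw_candidate_web",
    "count_components",
    "generate_web",
]


class NicheModelError(ValueError):
    """Invalid niche-model parameters."""


class WebGenerationError(RuntimeError):
    """Rejection sampling exhausted without an acceptable web."""


@dataclass
class TopologicalWeb:
    """A directed food-web topology.

    ``A[i, j] == 1`` means species i consumes species j, i.e. energy flows
    from column j to row i.  Species indices are 0-based.
    """

    S: int
    C_target: float
    n: np.ndarray  # niche values, shape (S,)
    r: np.ndarray  # feeding-range widths
    c: np.ndarray  # feeding-range centers
    A: np.ndarray  # S x S binary adjacency (int8), consumer rows
    attempts: int = 1  # candidate draws consumed to obtain this web

    @property
    def L(self) -> int:
        """Number of realized directed links."""
        return int(self.A.sum())

    @property
    def connectance(self) -> float:
        """Realized connectance L / S**2."""
        return self.L / self.S**2

    def producers(self) -> np.ndarray:
        """Indices of basal species (rows of A that are all zero)."""
        return np.flatnonzero(self.A.sum(axis=1) == 0)


def beta_shape(C: float) -> float:
    """Beta-distribution shape parameter beta = (1 - 2C) / (2C).

    With alpha = 1 this gives E[b] = 2C, so widths r = n * b have mean C
    (niche values average 0.5), calibrating realized connectance to C.
    """
    if not 0.0 < C < 0.5:
        raise NicheModelError(
            f"connectance must lie in (0, 0.5), got {C} "
            "(beta shape (1-2C)/(2C) undefined otherwise)"
        )
    return (1.0 - 2.0 * C) / (2.0 * C)


def draw_candidate_web(S: int, C: float, rng: np.random.Generator) -> TopologicalWeb:
    """Draw one niche-model web at target size S and connectance C.

    No validity tests are applied; see :func:`generate_web` for the
    rejection-sampled version.
    """
    if S < 1:
        raise NicheModelError(f"species count must be >= 1, got {S}")
    beta = beta_shape(C)

    n = rng.uniform(0.0, 1.0, size=S)
    b = rng.beta(1.0, beta, size=S)
    r = n * b
    # center anywhere in [r/2, n]: range cannot extend below 0 on the left
    c = rng.uniform(r / 2.0, n)

    lo = c - r / 2.0
    hi = c + r / 2.0
    A = ((n[None, :] >= lo[:, None]) & (n[None, :] <= hi[:, None])).astype(np.int8)
    return TopologicalWeb(S=S, C_target=C, n=n, r=r, c=c, A=A)


def count_components(A: np.ndarray, tol_scale: float = 1e-9) -> int:
    """Number of connected components via the Laplacian spectrum.

    Builds the undirected adjacency with self-loops removed, forms
    L = D - A_und and counts eigenvalues with ``|lambda| < tol_scale * S``
    (Laplacian eigenvalues are O(S), so the zero test is scaled).
    """
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    S = A.shape[0]
    und = ((A != 0) | (A.T != 0)).astype(float)
    np.fill_diagonal(und, 0.0)
    lap = np.diag(und.sum(axis=1)) - und
    eig = np.linalg.eigvalsh(lap)
    return int(np.sum(np.abs(eig) < tol_scale * max(S, 1)))


def _is_valid(web: TopologicalWeb) -> bool:
    has_producer = web.producers().size > 0
    return has_producer and count_components(web.A) == 1


def generate_web(
    S: int,
    C: float,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> TopologicalWeb:
    """Rejection-sample a valid niche-model web.

    A candidate is accepted when it has at least one producer and exactly
    one connected component.  The returned web records how many candidate
    draws were consumed in ``attempts``.
    """
    if max_attempts < 1:
        raise NicheModelError("max_attempts must be >= 1")
    for attempt in range(1, max_attempts + 1):
        web = draw_candidate_web(S, C, rng)
        if _is_valid(web):
            web.attempts = attempt
            return web
    raise WebGenerationError(
        f"no valid web found for (S={S}, C={C}) in {max_attempts} attempts"
    )
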