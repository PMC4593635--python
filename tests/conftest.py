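import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from nicheflow.nichemodel import TopologicalWeb
from nicheflow.trophic import parametrize

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_rng(seed: int = 0) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))


def web_from_adjacency(A) -> TopologicalWeb:
    """Handcrafted topology; niche attributes are placeholders."""
    A = np.asarray(A, dtype=np.int8)
    S = A.shape[0]
    return TopologicalWeb(
        S=S,
        C_target=max(min(A.sum() / S**2, 0.49), 0.01),
        n=np.linspace(0.1, 0.9, S),
        r=np.zeros(S),
        c=np.zeros(S),
        A=A,
    )


@pytest.fixture
def rng():
    return make_rng(0)


@pytest.fixture
def chain3():
    """C eats B eats A (species 0 basal)."""
    return web_from_adjacency([[0, 0, 0], [1, 0, 0], [0, 1, 0]])


@pytest.fixture
def omnivore3():
    """A basal; B eats A; C eats both A and B."""
    return web_from_adjacency([[0, 0, 0], [1, 0, 0], [1, 1, 0]])


@pytest.fixture
def two_species():
    """Producer and one consumer."""
    return web_from_adjacency([[0, 0], [1, 0]])


@pytest.fixture
def pweb2(two_species):
    return parametrize(two_species)


def random_parametrized_webs(n, S, C, seed=0):
    """Generate up to n valid parametrized webs (skipping trophic failures)."""
    from nicheflow.nichemodel import generate_web
    from nicheflow.trophic import TrophicError

    rng = make_rng(seed)
    out = []
    attempts = 0
    while len(out) < n and attempts < 20 * n:
        attempts += 1
        web = generate_web(S, C, rng)
        try:
            out.append(parametrize(web))
        except TrophicError:
            continue
    return out
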