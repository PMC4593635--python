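"""Bioenergetic dynamics: functional response, derivatives, RK4, protocol."""

import numpy as np
import pytest

from nicheflow.dynamics import (
    EXTINCTION_THRESHOLD,
    biomass_derivative,
    functional_response,
    functional_response_matrix,
    integrate,
    run_protocol,
)
from nicheflow.trophic import parametrize, TrophicError
from nicheflow.nichemodel import generate_web

from conftest import make_rng, web_from_adjacency


def test_functional_response_hand_value(pweb2):
    # single prey, B_i = B_j = 0.5, q = c = 1, B0 = 0.5:
    # 0.25 / (0.25 + 0.125 + 0.25) = 0.4
    assert functional_response([0.5, 0.5], pweb2, 1, 0) == pytest.approx(0.4)


def test_functional_response_saturates(pweb2):
    val = functional_response([1e6, 0.5], pweb2, 1, 0)
    assert val == pytest.approx(1.0, abs=1e-4)


def test_functional_response_zero_prey(pweb2):
    assert functional_response([0.0, 0.5], pweb2, 1, 0) == 0.0


def test_functional_response_requires_link(pweb2):
    with pytest.raises(ValueError):
        functional_response([0.5, 0.5], pweb2, 0, 1)


def test_lone_producer_derivative():
    pweb = parametrize(web_from_adjacency([[0]]))
    assert biomass_derivative([1.0], pweb)[0] == pytest.approx(0.0)
    assert biomass_derivative([0.5], pweb)[0] == pytest.approx(0.25)


def test_two_species_derivative_matches_hand_evaluation(pweb2):
    B = np.array([0.5, 0.5])
    F = 0.4
    x_c = 0.314 * 10**-0.25
    gain = x_c * 8 * 0.5 * F
    dB_expected = np.array([
        1 * 0.5 * (1 - 0.5) - gain / 0.45,  # producer: logistic - predation
        -x_c * 0.5 + gain,                  # consumer: metabolism + assimilated
    ])
    assert biomass_derivative(B, pweb2) == pytest.approx(dB_expected, rel=1e-12)


def test_jit_rhs_agrees_with_reference_derivative():
    """The compiled inner-loop right-hand side must match the vectorized
    reference implementation on random webs and random states."""
    from nicheflow.dynamics import _rhs, _prey_csr

    rng = make_rng(21)
    checked = 0
    while checked < 10:
        web = generate_web(12, 0.2, rng)
        try:
            pweb = parametrize(web)
        except TrophicError:
            continue
        B = rng.uniform(0.0, 1.5, size=web.S)
        indptr, indices = _prey_csr(pweb.A)
        out = np.empty(web.S)
        bq = np.empty(web.S)
        _rhs(B, bq, indptr, indices, pweb.x, 1.0 / pweb.e_col, pweb.r, pweb.K,
             pweb.is_producer, pweb.y, pweb.q, pweb.c, pweb.B0, out)
        assert out == pytest.approx(biomass_derivative(B, pweb), rel=1e-12, abs=1e-14)
        checked += 1


def test_integration_matches_logistic_closed_form():
    pweb = parametrize(web_from_adjacency([[0]]))
    states = integrate(pweb, [0.5], duration=5, dt=0.01)
    t = np.arange(6)
    exact = 1.0 / (1.0 + np.exp(-t))  # B(0)=0.5, r=K=1
    assert states[:, 0] == pytest.approx(exact, abs=1e-6)


def test_isolated_consumer_decays_exponentially():
    # a consumer with no prey or predators follows dB/dt = -x B
    pweb = parametrize(web_from_adjacency([[0, 0], [1, 0]])).subset(np.array([1]))
    assert not pweb.is_producer[0]
    states = integrate(pweb, [0.8], duration=1, dt=0.01)
    assert states[1, 0] / states[0, 0] == pytest.approx(np.exp(-pweb.x[0]), abs=1e-9)
    # monotone decay: the fate of a consumer whose sole prey was removed
    longer = integrate(pweb, [0.8], duration=20, dt=0.01)
    assert np.all(np.diff(longer[:, 0]) < 0)


def test_zero_duration_returns_initial_state(pweb2):
    states = integrate(pweb2, [0.6, 0.7], duration=0, dt=0.01)
    assert states.shape == (1, 2)
    assert states[0] == pytest.approx([0.6, 0.7])


def test_dt_must_divide_time_unit(pweb2):
    with pytest.raises(ValueError):
        integrate(pweb2, [0.5, 0.5], duration=1, dt=0.03)


def test_rk4_step_halving_converges():
    """Halving dt changes integer-time biomasses by far less than 1e-6."""
    rng = make_rng(22)
    web = generate_web(10, 0.2, rng)
    pweb = parametrize(web)
    B0 = rng.uniform(0.5, 1.0, size=10)
    a = integrate(pweb, B0, duration=20, dt=0.02)
    b = integrate(pweb, B0, duration=20, dt=0.01)
    assert np.max(np.abs(a - b)) < 1e-6


def test_protocol_producers_only_reach_carrying_capacity():
    pweb = parametrize(web_from_adjacency(np.zeros((4, 4), dtype=int)))
    sim = run_protocol(pweb, make_rng(3), duration_phase1=50, duration_phase2=50)
    assert sim.extinct_ids.size == 0
    assert not sim.degenerate
    assert sim.trajectory[-1] == pytest.approx(np.ones(4), abs=1e-6)


def test_protocol_is_bit_reproducible():
    web = generate_web(10, 0.2, make_rng(5))
    pweb = parametrize(web)
    s1 = run_protocol(pweb, make_rng(17), duration_phase1=30, duration_phase2=30)
    s2 = run_protocol(pweb, make_rng(17), duration_phase1=30, duration_phase2=30)
    assert np.array_equal(s1.trajectory, s2.trajectory)
    assert np.array_equal(s1.surviving_ids, s2.surviving_ids)
    assert s1.steady_state_gap == s2.steady_state_gap


def test_protocol_removes_species_once_between_phases():
    rng = make_rng(31)
    found = False
    for _ in range(30):
        web = generate_web(12, 0.2, rng)
        try:
            pweb = parametrize(web)
        except TrophicError:
            continue
        sim = run_protocol(pweb, rng, duration_phase1=200, duration_phase2=50)
        if sim.degenerate or sim.extinct_ids.size == 0:
            continue
        found = True
        assert set(sim.extinct_ids) & set(sim.surviving_ids) == set()
        assert sim.surviving_web.S == sim.surviving_ids.size
        assert sim.trajectory.shape == (51, sim.surviving_ids.size)
        break
    assert found, "no run with extinctions encountered"


def test_steady_state_gap_shrinks_with_duration():
    """Phase-2 runs approach steady state: max |dB/dt| decreases along a
    logarithmic sampling of durations."""
    web = generate_web(10, 0.2, make_rng(41))
    pweb = parametrize(web)
    B0 = make_rng(42).uniform(0.5, 1.0, size=10)
    gaps = []
    for dur in (10, 100, 1000):
        states = integrate(pweb, B0, duration=dur, dt=0.01)
        gaps.append(np.max(np.abs(biomass_derivative(states[-1], pweb))))
    assert gaps[0] > gaps[1] > gaps[2]


def test_functional_response_matrix_rows_bounded():
    rng = make_rng(51)
    web = generate_web(10, 0.25, rng)
    pweb = parametrize(web)
    F = functional_response_matrix(rng.uniform(0, 2, size=10), pweb)
    assert (F >= 0).all() and (F <= 1).all()
    assert (F.sum(axis=1) <= 1 + 1e-12).all()
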