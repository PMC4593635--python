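"""Flow snapshots, G normalization, integral flow N, and flow indirectness."""

import itertools

import numpy as np
import pytest

from nicheflow.dynamics import biomass_derivative, run_protocol
from nicheflow.environ import (
    flow_indirectness,
    flow_snapshot,
    integral_flow,
    normalized_flow_matrix,
    run_dea,
    FlowSnapshot,
)
from nicheflow.nichemodel import generate_web
from nicheflow.trophic import parametrize, TrophicError

from conftest import make_rng, web_from_adjacency


# --- snapshots ------------------------------------------------------------

def test_snapshot_two_species_hand_arithmetic(pweb2):
    B = np.array([0.5, 0.5])
    snap = flow_snapshot(B, pweb2)
    # assimilated flow: x_c * y * B_c * F = 0.17658 * 8 * 0.5 * 0.4
    assert snap.f[1, 0] == pytest.approx(0.28252, abs=1e-5)
    # prey loses the pre-assimilation amount f / 0.45
    pre = snap.f[1, 0] / 0.45
    assert pre == pytest.approx(0.62782, abs=1e-5)
    # with producer respiration, producer t_out adds 0.138 * 0.5 = 0.069
    assert snap.t_out[0] == pytest.approx(pre + 0.069)
    G = normalized_flow_matrix(snap)
    assert G[1, 0] == pytest.approx(0.40544, abs=1e-5)
    # without producer respiration the producer column normalizes to e = 0.45
    snap2 = flow_snapshot(B, pweb2, producer_respiration=False)
    assert normalized_flow_matrix(snap2)[1, 0] == pytest.approx(0.45)


def test_snapshot_producer_at_capacity():
    pweb = parametrize(web_from_adjacency([[0]]))
    snap = flow_snapshot(np.array([1.0]), pweb, producer_respiration=False)
    assert snap.z[0] == 0.0
    assert snap.f.sum() == 0.0
    assert snap.z[0] + snap.f[0].sum() - snap.t_out[0] == pytest.approx(0.0)


@pytest.mark.parametrize("respiration", [True, False])
def test_node_balance_matches_ode_rhs(respiration):
    """Energy conservation: dB_j/dt = z_j + inflows_j - t_out_j at every
    snapshot, against the independent derivative implementation."""
    rng = make_rng(61)
    checked = 0
    while checked < 10:
        web = generate_web(12, 0.2, rng)
        try:
            pweb = parametrize(web)
        except TrophicError:
            continue
        B = rng.uniform(0.0, 1.5, size=web.S)
        snap = flow_snapshot(B, pweb, producer_respiration=respiration)
        balance = snap.z + snap.f.sum(axis=1) - snap.t_out
        assert balance == pytest.approx(biomass_derivative(B, pweb), abs=1e-9)
        checked += 1


def test_cannibal_self_flow_excluded_from_g_but_in_t_out():
    # species 1 eats the producer and itself
    web = web_from_adjacency([[0, 0], [1, 1]])
    pweb = parametrize(web)
    B = np.array([0.6, 0.4])
    snap = flow_snapshot(B, pweb)
    assert snap.f[1, 1] > 0
    G = normalized_flow_matrix(snap)
    assert G[1, 1] == 0.0
    # removing the self-flow from t_out would change the other entry
    assert G[1, 0] == pytest.approx(snap.f[1, 0] / snap.t_out[0])
    assert snap.t_out[1] >= snap.f[1, 1] / pweb.e_col[1]


def test_zero_flow_matrix_normalizes_to_zero():
    snap = FlowSnapshot(f=np.zeros((3, 3)), z=np.zeros(3), o=np.zeros(3),
                        t_out=np.zeros(3))
    assert np.array_equal(normalized_flow_matrix(snap), np.zeros((3, 3)))


def test_inconsistent_snapshot_raises():
    f = np.zeros((2, 2))
    f[1, 0] = 0.3  # outflow from species 0 with zero recorded t_out
    snap = FlowSnapshot(f=f, z=np.zeros(2), o=np.zeros(2), t_out=np.zeros(2))
    with pytest.raises(ValueError):
        normalized_flow_matrix(snap)


# --- integral flow --------------------------------------------------------

def test_integral_flow_zero_g_gives_identity():
    Gs = [np.zeros((4, 4))] * 21
    assert np.array_equal(integral_flow(Gs, 20), np.eye(4))


def test_integral_flow_acyclic_example():
    # g_BA = 0.3, g_CA = 0.4, g_BC = 0.5 (indices A=0, B=1, C=2)
    G = np.zeros((3, 3))
    G[1, 0], G[2, 0], G[1, 2] = 0.3, 0.4, 0.5
    N = integral_flow([G] * 21, 20)
    assert N[1, 0] == pytest.approx(0.3 + 0.5 * 0.4)
    assert N[2, 0] == pytest.approx(0.4)
    assert np.allclose(np.diag(N), 1.0)


def test_integral_flow_matches_neumann_inverse():
    """With constant substochastic G and a long window, N approaches
    (I - G)^-1."""
    rng = make_rng(71)
    G = rng.uniform(0, 1, (5, 5))
    G *= 0.9 / G.sum(axis=0).max()  # spectral radius < 1
    np.fill_diagonal(G, 0.0)
    N = integral_flow([G] * 51, 50)
    expected = np.linalg.inv(np.eye(5) - G)
    assert N == pytest.approx(expected, abs=1e-6)


def test_integral_flow_nondecreasing_in_window():
    rng = make_rng(72)
    G = rng.uniform(0, 0.2, (6, 6))
    np.fill_diagonal(G, 0.0)
    Gs = [G] * 31
    prev = integral_flow(Gs, 0)
    for m in (1, 2, 5, 10, 30):
        cur = integral_flow(Gs, m)
        assert (cur >= prev - 1e-15).all()
        prev = cur


def test_integral_flow_window_requires_enough_matrices():
    with pytest.raises(ValueError):
        integral_flow([np.zeros((2, 2))] * 3, 5)


# --- flow indirectness ----------------------------------------------------

def test_fi_three_species_example():
    G = np.zeros((3, 3))
    G[1, 0], G[2, 0], G[1, 2] = 0.3, 0.4, 0.5
    A = (G > 0).astype(int)
    N = integral_flow([G] * 21, 20)
    FI, mean_fi, valid = flow_indirectness(N, G, A)
    assert FI[1, 0] == pytest.approx(0.2 / 0.5)
    assert mean_fi == pytest.approx(0.4 / 3)
    assert valid


def test_fi_difference_definition():
    G = np.zeros((3, 3))
    G[1, 0], G[2, 0], G[1, 2] = 0.3, 0.4, 0.5
    A = (G > 0).astype(int)
    N = integral_flow([G] * 21, 20)
    FI, mean_fi, valid = flow_indirectness(N, G, A, definition="difference")
    assert FI[1, 0] == pytest.approx(0.2)
    assert mean_fi == pytest.approx(0.2 / 3)
    assert valid
    with pytest.raises(ValueError):
        flow_indirectness(N, G, A, definition="nonsense")


def test_fi_matches_path_enumeration_oracle():
    """On random acyclic G, FI equals a brute-force sum over enumerated
    directed paths of length 2..m."""
    rng = make_rng(81)
    S, m = 8, 20
    for _ in range(10):
        # random DAG: upper-triangular flow pattern
        G = np.triu(rng.uniform(0, 0.5, (S, S)), 1).T  # flows low->high index
        keep = rng.random((S, S)) < 0.4
        G = np.where(keep, G, 0.0)
        A = (G > 0).astype(int)
        # brute-force: sum products over all simple paths j -> ... -> i
        N_paths = np.zeros((S, S))
        def extend(path, product):
            j = path[0]
            i = path[-1]
            if len(path) > 1:
                N_paths[i, j] += product
            if len(path) - 1 == m:
                return
            for k in range(S):
                if G[k, i] > 0:
                    extend(path + [k], product * G[k, i])
        for j in range(S):
            extend([j], 1.0)
        N = integral_flow([G] * (m + 1), m)
        assert N == pytest.approx(np.eye(S) + N_paths, abs=1e-12)
        FI, _, _ = flow_indirectness(N, G, A)
        want = np.zeros((S, S))
        pos = N_paths + np.eye(S) > 0
        want[pos] = (N_paths[pos] + np.eye(S)[pos] - G[pos]) / (N_paths[pos] + np.eye(S)[pos])
        np.fill_diagonal(want, 0.0)
        assert FI == pytest.approx(want, abs=1e-12)


def test_two_species_web_has_zero_indirectness(pweb2):
    sim = run_protocol(pweb2, make_rng(9), duration_phase1=100, duration_phase2=100)
    dea = run_dea(sim)
    assert dea.valid
    assert dea.mean_FI == pytest.approx(0.0)


def test_run_dea_steady_state_consistency():
    """At steady state every G in the window is identical and N equals the
    truncated Neumann series of that G."""
    rng = make_rng(91)
    web = generate_web(10, 0.2, rng)
    pweb = parametrize(web)
    sim = run_protocol(pweb, rng)
    dea = run_dea(sim)
    assert not dea.degenerate
    G0 = dea.G_series[0]
    for G in dea.G_series[1:]:
        assert G == pytest.approx(G0, abs=1e-7)
    assert dea.N == pytest.approx(sum(np.linalg.matrix_power(G0, k) for k in range(21)),
                                  abs=1e-5)


def test_run_dea_producers_only_is_degenerate():
    pweb = parametrize(web_from_adjacency(np.zeros((3, 3), dtype=int)))
    sim = run_protocol(pweb, make_rng(2), duration_phase1=50, duration_phase2=50)
    dea = run_dea(sim)
    assert dea.degenerate
    assert not dea.valid
    assert np.isnan(dea.mean_FI)


def test_mean_fi_in_unit_interval_over_random_runs():
    rng = make_rng(101)
    checked = 0
    while checked < 12:
        web = generate_web(10, 0.2, rng)
        try:
            pweb = parametrize(web)
        except TrophicError:
            continue
        sim = run_protocol(pweb, rng, duration_phase1=300, duration_phase2=100)
        if sim.degenerate:
            continue
        dea = run_dea(sim)
        if dea.degenerate:
            continue
        assert 0.0 <= dea.mean_FI <= 1.0
        assert 0.0 <= dea.mean_FI_ratio <= 1.0
        checked += 1


def test_run_dea_window_longer_than_trajectory_errors(pweb2):
    sim = run_protocol(pweb2, make_rng(4), duration_phase1=50, duration_phase2=10)
    with pytest.raises(ValueError):
        run_dea(sim, window=20)
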