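"""Six-state chain: stationary distribution, closed forms, event-driven simulator."""

import numpy as np
import pytest

from pulsespread.kinetics import (
    FilamentState,
    KineticParameters,
    generator_matrix,
    simulate_trajectory,
    stationary_distribution,
    theoretical_slopes,
    theoretical_velocity,
    _simulate_displacements,
)

S = FilamentState


def test_generator_structure(default_params):
    """Rows sum to zero and only the allowed transitions carry rate."""
    Q = generator_matrix(default_params)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-15)
    allowed = {
        (S.ANTERO_RUN, S.ANTERO_PAUSE_ON),
        (S.ANTERO_PAUSE_ON, S.ANTERO_RUN),
        (S.ANTERO_PAUSE_ON, S.ANTERO_PAUSE_OFF),
        (S.ANTERO_PAUSE_OFF, S.ANTERO_PAUSE_ON),
        (S.RETRO_RUN, S.RETRO_PAUSE_ON),
        (S.RETRO_PAUSE_ON, S.RETRO_RUN),
        (S.RETRO_PAUSE_ON, S.RETRO_PAUSE_OFF),
        (S.RETRO_PAUSE_OFF, S.RETRO_PAUSE_ON),
        (S.ANTERO_PAUSE_ON, S.RETRO_PAUSE_ON),
        (S.RETRO_PAUSE_ON, S.ANTERO_PAUSE_ON),
    }
    for i in range(6):
        for j in range(6):
            if i != j and Q[i, j] > 0:
                assert (S(i), S(j)) in allowed


def test_stationary_sums_to_one(default_params):
    ss = stationary_distribution(default_params)
    assert ss.as_array().sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(ss.as_array() >= 0)


def test_stationary_symmetric_params_balance():
    """With identical anterograde and retrograde rates, p_a = p_r."""
    p = KineticParameters(rate_reverse_a_to_r=0.01, rate_reverse_r_to_a=0.01)
    ss = stationary_distribution(p)
    assert ss.p_a == pytest.approx(ss.p_r, rel=1e-10)
    assert ss.p_pause_off_a == pytest.approx(ss.p_pause_off_r, rel=1e-10)


def test_stationary_reversal_ratio_sets_bias(default_params):
    """On the tree topology, p_a/p_r equals the reversal-rate ratio r->a / a->r."""
    ss = stationary_distribution(default_params)
    expected = default_params.rate_reverse_r_to_a / default_params.rate_reverse_a_to_r
    assert ss.p_a / ss.p_r == pytest.approx(expected, rel=1e-9)


def test_stationary_one_directional_limit():
    """No entry into the retrograde side: all retrograde occupancy vanishes."""
    p = KineticParameters(rate_reverse_a_to_r=0.0, rate_reverse_r_to_a=0.05)
    ss = stationary_distribution(p)
    assert ss.p_r == 0.0
    assert ss.p_pause_on_r == 0.0
    assert ss.p_pause_off_r == 0.0
    assert theoretical_velocity(p) == pytest.approx(ss.p_a * p.v_a)


def test_stationary_reducible_chain_errors():
    """Both reversal rates zero disconnect the directions: explicit error."""
    p = KineticParameters(rate_reverse_a_to_r=0.0, rate_reverse_r_to_a=0.0)
    with pytest.raises(ValueError, match="reducible"):
        stationary_distribution(p)


def test_all_zero_rates_error():
    p = KineticParameters(
        rate_run_to_pause_on=0, rate_pause_on_to_run=0, rate_on_to_off=0,
        rate_off_to_on=0, rate_reverse_a_to_r=0, rate_reverse_r_to_a=0,
    )
    with pytest.raises(ValueError):
        stationary_distribution(p)


def test_parameter_validation():
    with pytest.raises(ValueError):
        KineticParameters(v_a=0.0)
    with pytest.raises(ValueError):
        KineticParameters(filament_length=-1.0)
    with pytest.raises(ValueError):
        KineticParameters(rate_on_to_off=-0.1)


def test_stationary_matches_long_run_occupancy(fast_params):
    """Monte-Carlo oracle: time-averaged state occupancy over >= 1e6 s of
    trajectory matches the linear-algebra stationary fractions within 1%."""
    ss = stationary_distribution(fast_params).as_array()
    occ = np.zeros(6)
    total = 0.0
    rng = np.random.default_rng(42)
    for k in range(60):
        traj = simulate_trajectory(fast_params, 20000.0, S(int(np.argmax(ss))), rng)
        for (t0, _, st), (t1, _, _) in zip(traj.events[:-1], traj.events[1:]):
            occ[int(st)] += t1 - t0
        total += traj.duration
    assert total >= 1e6
    occ /= occ.sum()
    assert np.max(np.abs(occ - ss)) < 0.01


def test_theoretical_velocity_symmetry_zero():
    p = KineticParameters(v_a=0.5, v_r=0.5, rate_reverse_a_to_r=0.02, rate_reverse_r_to_a=0.02)
    assert theoretical_velocity(p) == pytest.approx(0.0, abs=1e-12)


def test_theoretical_velocity_monte_carlo(fast_params):
    """Ensemble mean displacement / time over 10,000 trajectories agrees with
    p_a v_a - p_r v_r within 3 standard errors."""
    v_th = theoretical_velocity(fast_params)
    rng = np.random.default_rng(7)
    ss = stationary_distribution(fast_params).as_array()
    n = 10000
    T = 400.0
    states0 = rng.choice(6, size=n, p=ss)
    disp = _simulate_displacements(fast_params, states0, np.array([T]), rng)[:, 0]
    v_est = disp.mean() / T
    se = disp.std(ddof=1) / np.sqrt(n) / T
    assert abs(v_est - v_th) < 3 * se


def test_theoretical_slopes_scaling_and_limits(default_params):
    S_p1, S_d1 = theoretical_slopes(default_params, 40.0)
    S_p2, S_d2 = theoretical_slopes(default_params, 80.0)
    assert S_p1 == pytest.approx(2 * S_p2)
    assert S_d1 == pytest.approx(2 * S_d2)
    one_way = KineticParameters(rate_reverse_a_to_r=0.0, rate_reverse_r_to_a=0.05)
    S_p, S_d = theoretical_slopes(one_way, 40.0)
    assert S_p == 0.0
    assert S_d > 0
    with pytest.raises(ValueError):
        theoretical_slopes(default_params, 0.0)


def test_trajectory_no_transitions_is_constant():
    p = KineticParameters(
        rate_run_to_pause_on=0, rate_pause_on_to_run=0, rate_on_to_off=0,
        rate_off_to_on=0, rate_reverse_a_to_r=0, rate_reverse_r_to_a=0,
    )
    traj = simulate_trajectory(p, 100.0, S.ANTERO_PAUSE_OFF, seed=0)
    assert len(traj.events) == 2
    assert traj.events[-1][1] == 0.0


def test_trajectory_pure_run_is_linear():
    """A filament locked in the anterograde run state moves at exactly v_a."""
    p = KineticParameters(
        rate_run_to_pause_on=0, rate_pause_on_to_run=0, rate_on_to_off=0,
        rate_off_to_on=0, rate_reverse_a_to_r=0, rate_reverse_r_to_a=0,
    )
    traj = simulate_trajectory(p, 50.0, S.ANTERO_RUN, seed=0)
    t = np.linspace(0, 50.0, 11)
    assert np.allclose(traj.position_at(t), p.v_a * t, atol=1e-12)


def test_trajectory_event_times_increase_and_states_allowed(fast_params):
    traj = simulate_trajectory(fast_params, 5000.0, S.ANTERO_PAUSE_ON, seed=3)
    times = [e[0] for e in traj.events]
    assert all(t1 > t0 for t0, t1 in zip(times[:-2], times[1:-1]))
    Q = generator_matrix(fast_params)
    for (_, _, s0), (_, _, s1) in zip(traj.events[:-2], traj.events[1:-1]):
        if s0 != s1:
            assert Q[int(s0), int(s1)] > 0


def test_mean_dwell_times_match_exit_rates(fast_params):
    """Mean sojourn duration in each state ~ 1/(total exit rate) within 2%
    over >= 10,000 sojourns (exponential waiting-time oracle)."""
    Q = generator_matrix(fast_params)
    exit_rates = -np.diag(Q)
    dwell_sum = np.zeros(6)
    dwell_n = np.zeros(6)
    rng = np.random.default_rng(11)
    while dwell_n.min() < 10000:
        traj = simulate_trajectory(fast_params, 20000.0, S.ANTERO_PAUSE_ON, rng)
        for (t0, _, st), (t1, _, _) in zip(traj.events[:-2], traj.events[1:-1]):
            dwell_sum[int(st)] += t1 - t0
            dwell_n[int(st)] += 1
    for s in range(6):
        assert dwell_sum[s] / dwell_n[s] == pytest.approx(1.0 / exit_rates[s], rel=0.02)


def test_trajectory_seed_determinism(fast_params):
    t1 = simulate_trajectory(fast_params, 1000.0, S.ANTERO_RUN, seed=5)
    t2 = simulate_trajectory(fast_params, 1000.0, S.ANTERO_RUN, seed=5)
    assert t1.events == t2.events


def test_invalid_inputs(fast_params):
    with pytest.raises(ValueError):
        simulate_trajectory(fast_params, -1.0, S.ANTERO_RUN, seed=0)
    with pytest.raises(ValueError):
        simulate_trajectory(fast_params, 10.0, 17, seed=0)
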