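"""Hill responses, activation calibration, agent stepping, simulation loop."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest

import fibronet as fn
from fibronet.agents import AgentState, ResponseParams, agent_step, calibrated
from fibronet.exceptions import InvalidStateError


def random_admissible_params(rng) -> ResponseParams:
    return ResponseParams(
        w1=rng.uniform(0.0, 2.0),
        w2=rng.uniform(0.0, 2.0),
        eps50=rng.uniform(0.02, 0.3),
        n_eps=rng.uniform(1.0, 8.0),
        amp_eps=rng.uniform(0.5, 2.0),
        k50=rng.uniform(1.0, 10.0),
        n_k=rng.uniform(1.0, 10.0),
        amp_k=rng.uniform(0.5, 2.0),
        delta=rng.uniform(0.01, 0.3),
        eps_home=rng.uniform(0.02, 0.3),
    )


class TestHillResponse:
    @pytest.mark.parametrize(
        "value,half,n,amp,expected",
        [
            (0.3, 0.3, 2.0, 1.7, 0.85),  # midpoint identity
            (0.0, 0.3, 2.0, 1.0, 0.0),
            (0.6, 0.3, 2.0, 1.0, 0.8),  # 4/(1+4)
            (-0.2, 0.3, 2.0, 1.0, 0.0),  # compression clamps to zero
        ],
    )
    def test_values(self, value, half, n, amp, expected):
        assert fn.hill_response(value, half, n, amp) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(
        half=st.floats(0.01, 10.0),
        n=st.floats(1.0, 10.0),
        amp=st.floats(0.1, 5.0),
        a=st.floats(0.0, 50.0),
        b=st.floats(0.0, 50.0),
    )
    def test_monotone_and_bounded(self, half, n, amp, a, b):
        lo, hi = sorted((a, b))
        fa, fb = (fn.hill_response(v, half, n, amp) for v in (lo, hi))
        assert fa <= fb + 1e-12
        assert 0.0 <= fa <= amp and 0.0 <= fb <= amp


class TestCalibration:
    def test_reductions(self):
        p = ResponseParams(w1=1.0, w2=0.0)
        a_eps_home = fn.hill_response(p.eps_home, p.eps50, p.n_eps, p.amp_eps)
        assert fn.calibrate_c(p) == pytest.approx(a_eps_home)
        assert fn.calibrate_c(ResponseParams(w1=0.0, w2=0.0)) == 0.0

    def test_zero_activation_at_set_point_100_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            p = calibrated(random_admissible_params(rng))
            a = fn.total_activation(p.eps_home, p.k0 * p.csa_home, p)
            assert abs(a) < 1e-12

    def test_signs_around_set_point(self, params):
        assert fn.total_activation(3 * params.eps_home, params.k0, params) > 0
        assert fn.total_activation(0.0, params.k0, params) < 0

    def test_uncalibrated_raises(self):
        with pytest.raises(InvalidStateError):
            fn.total_activation(0.1, 1.0, ResponseParams())

    def test_fibrotic_threshold_is_emergent(self, params):
        k_star = fn.fibrotic_threshold_stiffness(params)
        assert k_star is not None and k_star > params.k0
        assert fn.total_activation(0.0, 0.99 * k_star, params) < 0
        assert fn.total_activation(0.0, 1.01 * k_star, params) > 0
        # pure negative feedback: no threshold exists
        assert fn.fibrotic_threshold_stiffness(ResponseParams(w2=0.0)) is None


class TestCsaUpdate:
    def test_zero_activation_no_change(self, params):
        assert fn.update_spring_csa(1.7, 0.0, params) == 1.7

    def test_signs(self, params):
        assert fn.update_spring_csa(2.0, 0.5, params) > 2.0
        assert fn.update_spring_csa(2.0, -0.5, params) < 2.0

    def test_floor_and_ceiling(self, params):
        assert fn.update_spring_csa(0.11, -5.0, params) == params.csa_min
        assert fn.update_spring_csa(params.csa_max, 5.0, params) == params.csa_max

    @settings(derandomize=True, max_examples=60)
    @given(csa=st.floats(0.1, 50.0), a=st.floats(-3.0, 3.0))
    def test_stays_in_bounds(self, csa, a, params):
        new = fn.update_spring_csa(csa, a, params)
        assert params.csa_min <= new <= params.csa_max
        assert np.isfinite(new)


class TestAgentStep:
    def test_degree_one_node_forced_traversal(self, fixtures, params):
        star = fixtures["star"].copy()
        agent = AgentState(0, node=1)  # a leaf: single incident spring
        rng = np.random.default_rng(0)
        stepped = agent_step(agent, star, params, rng)
        assert stepped.node == 0
        assert stepped.last_spring == 0

    def test_homeostatic_step_leaves_csa_unchanged(self, small_net, params):
        net = small_net.copy()
        rng = np.random.default_rng(1)
        agent = AgentState(0, node=int(np.flatnonzero(~net.is_boundary)[0]))
        agent_step(agent, net, params, rng)
        assert np.all(net.csa == 1.0)

    def test_uniform_spring_choice_at_degree_3_node(self, small_net, params):
        net = small_net.copy()
        incident = net.incident_springs()
        node = next(
            i for i in range(net.n_nodes) if len(incident[i]) == 3
        )
        rng = np.random.default_rng(99)
        counts = {int(j): 0 for j in incident[node]}
        n_steps = 10_000
        for _ in range(n_steps):
            agent = AgentState(0, node=node)
            stepped = agent_step(agent, net, params, rng, incident)
            counts[stepped.last_spring] += 1
        for c in counts.values():
            # exact binomial test against p = 1/3
            assert binomtest(c, n_steps, 1 / 3).pvalue > 1e-4


class TestRunSimulation:
    def test_zero_iterations(self, small_net, params):
        traj = fn.run_simulation(small_net, None, n_iterations=0, params=params)
        assert traj.iterations.size == 0
        assert np.all(traj.network.csa == small_net.csa)

    def test_homeostatic_stability(self, small_net, params):
        traj = fn.run_simulation(
            small_net, None, n_iterations=500, params=params, rng_seed=11
        )
        base = traj.baseline_stiffness
        assert np.all(np.abs(traj.total_stiffness - base) <= 0.05 * base)

    def test_injury_imposed_at_injury_iteration(self, small_net, params):
        inj = fn.random_injury(small_net, 0.2, 5.0, rng_seed=5)
        traj = fn.run_simulation(
            small_net, inj, n_iterations=200, injury_iteration=150,
            params=params, rng_seed=11,
        )
        snap = traj.snapshots[150]
        for j in inj.assignments:
            assert snap[j] == 5.0
        before = traj.total_stiffness[:149]
        assert np.allclose(before, traj.baseline_stiffness, rtol=1e-9)

    def test_bit_identical_reruns(self, small_net, params):
        inj = fn.random_injury(small_net, 0.2, 5.0, rng_seed=5)
        kw = dict(n_iterations=180, injury_iteration=150, params=params, rng_seed=11)
        t1 = fn.run_simulation(small_net, inj, **kw)
        t2 = fn.run_simulation(small_net, inj, **kw)
        assert np.array_equal(t1.total_stiffness, t2.total_stiffness)
        assert np.array_equal(t1.final_csa, t2.final_csa)
        assert np.array_equal(
            t1.position_snapshots[180], t2.position_snapshots[180]
        )

    def test_csa_bounds_hold_over_trajectory(self, small_net, params):
        inj = fn.random_injury(small_net, 0.3, 5.0, rng_seed=8)
        traj = fn.run_simulation(
            small_net, inj, n_iterations=250, injury_iteration=50,
            params=params, rng_seed=3,
        )
        for snap in traj.snapshots.values():
            assert np.all(snap >= params.csa_min)
            assert np.all(snap <= params.csa_max)
            assert np.all(np.isfinite(snap))

    def test_injury_after_end_rejected(self, small_net, params):
        inj = fn.random_injury(small_net, 0.2, 5.0, rng_seed=5)
        with pytest.raises(ValueError):
            fn.run_simulation(
                small_net, inj, n_iterations=100, injury_iteration=150,
                params=params,
            )


class TestFeedbackRegimes:
    def test_negative_feedback_self_heals(self):
        """w2 = 0: sparse injury returns stiffness to a band around baseline."""
        net = fn.generate_voronoi_network(120, rng_seed=3)
        p = calibrated(ResponseParams(w2=0.0))
        inj = fn.random_injury(net, 0.05, 5.0, rng_seed=4)
        traj = fn.run_simulation(
            net, inj, n_iterations=800, injury_iteration=50, params=p, rng_seed=5
        )
        final = traj.total_stiffness[-1]
        assert abs(final - traj.baseline_stiffness) <= 0.05 * traj.baseline_stiffness

    def test_positive_feedback_amplifies_cluster(self):
        """Large w2 + large injured cluster: K non-decreasing in final quarter."""
        net = fn.generate_voronoi_network(120, rng_seed=3)
        p = calibrated(ResponseParams(w2=2.0))
        inj = fn.clustered_injury(net, 40, rng_seed=6)
        traj = fn.run_simulation(
            net, inj, n_iterations=600, injury_iteration=50, params=p, rng_seed=5
        )
        tail = traj.total_stiffness[-150:]
        slope = np.polyfit(np.arange(tail.size), tail, 1)[0]
        assert slope >= 0
        assert tail[-1] >= tail[0]
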