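"""Outcome classification, probability-by-CC, bisection, percolation,
and the 1D reduced model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import fibronet as fn
from fibronet.agents import Trajectory
from fibronet.analysis import HEALED, FIBROTIC
from fibronet.exceptions import InvalidStateError, NoCrossingError
from fibronet.network import SpatialNetwork


def synthetic_trajectory(net, q, K0, Ki, n=400, t0=50, noise=0.0, rng=None):
    """Trajectory whose stiffness trace follows the reduced-model closed form."""
    t = np.arange(1, n + 1)
    k = np.full(n, float(K0))
    post = t > t0
    k[post] = fn.reduced_model_solution(Ki, K0, q, (t[post] - t0).astype(float))
    if noise:
        k = k + rng.normal(scale=noise, size=n)
    snaps = {n: net.csa.copy()}
    return Trajectory(
        iterations=t,
        total_stiffness=k,
        snapshots=snaps,
        position_snapshots={n: net.positions.copy()},
        network=net,
        injury=None,
        injury_iteration=t0,
    )


@pytest.fixture(scope="module")
def tiny_net():
    return fn.generate_voronoi_network(40, rng_seed=2)


class TestFibrosisBoundSprings:
    def test_threshold_inclusive(self, tiny_net):
        inj = fn.random_injury(tiny_net, 0.2, 5.0, rng_seed=1)
        ids = sorted(inj.spring_ids)
        csa = np.ones(tiny_net.n_springs)
        csa[ids[0]] = 5.0   # exactly at threshold: included
        csa[ids[1]] = 4.99  # below: excluded
        traj = Trajectory(
            iterations=np.arange(1, 11),
            total_stiffness=np.full(10, float(tiny_net.n_springs)),
            snapshots={10: csa},
            position_snapshots={},
            network=tiny_net,
            injury=inj,
            injury_iteration=5,
        )
        bound = fn.fibrosis_bound_springs(traj, 5.0)
        assert ids[0] in bound and ids[1] not in bound

    def test_only_injured_springs_count(self, tiny_net):
        inj = fn.random_injury(tiny_net, 0.1, 5.0, rng_seed=1)
        csa = np.full(tiny_net.n_springs, 6.0)  # everything stiff
        traj = Trajectory(
            iterations=np.arange(1, 11),
            total_stiffness=np.full(10, 1.0),
            snapshots={10: csa},
            position_snapshots={},
            network=tiny_net,
            injury=inj,
            injury_iteration=5,
        )
        assert fn.fibrosis_bound_springs(traj) == inj.spring_ids

    def test_healed_run_empty(self, tiny_net):
        inj = fn.random_injury(tiny_net, 0.2, 5.0, rng_seed=1)
        traj = Trajectory(
            iterations=np.arange(1, 11),
            total_stiffness=np.full(10, 1.0),
            snapshots={10: np.ones(tiny_net.n_springs)},
            position_snapshots={},
            network=tiny_net,
            injury=inj,
            injury_iteration=5,
        )
        assert fn.fibrosis_bound_springs(traj) == frozenset()


class TestProbabilityByCC:
    def _mini_traj(self, net, stiff_at_t, final_stiff, inj):
        return Trajectory(
            iterations=np.arange(1, 21),
            total_stiffness=np.full(20, 1.0),
            snapshots={10: stiff_at_t, 20: final_stiff},
            position_snapshots={},
            network=net,
            injury=inj,
            injury_iteration=5,
        )

    def test_hand_tally_on_chain(self, fixtures):
        chain = fixtures["chain"]  # 5 springs in a row
        inj = fn.InjuryPattern({1: 5.0, 2: 5.0}, kind="custom")
        stiff_mid = np.array([1.0, 5.0, 5.0, 1.0, 1.0])
        final = np.array([1.0, 5.0, 1.0, 1.0, 1.0])  # only spring 1 bound
        traj = self._mini_traj(chain, stiff_mid, final, inj)
        table = fn.fibrotic_probability_by_cc([traj], [10])
        # stiff set at t=10 is {1, 2}: cc values 1..5 by hand:
        # spring0: gen1={1}, gen2={2} -> 2 ; spring1: self+2 -> 2
        # spring2: self+1 -> 2 ; spring3: {2}, gen2 {1} -> 2 ; spring4: {} gen1={3}? no -> 1?
        expect = {}
        for j in range(5):
            cc = fn.clustering_coefficient(chain, {1, 2}, j)
            expect.setdefault(cc, [0, 0])
            expect[cc][1] += 1
            if j == 1:
                expect[cc][0] += 1
        for _, row in table.iterrows():
            nb, nt = expect[row["cc"]]
            assert row["n_total"] == nt
            assert row["n_fibrosis_bound"] == nb
            assert row["probability"] == pytest.approx(nb / nt)

    def test_no_bound_springs_all_zero(self, fixtures):
        chain = fixtures["chain"]
        inj = fn.InjuryPattern({1: 5.0}, kind="custom")
        traj = self._mini_traj(
            chain, np.ones(5), np.ones(5), inj
        )
        table = fn.fibrotic_probability_by_cc([traj], [10])
        assert np.all(table["probability"] == 0)

    def test_pooling_across_trajectories(self, fixtures):
        chain = fixtures["chain"]
        inj = fn.InjuryPattern({1: 5.0}, kind="custom")
        stiff = np.array([1.0, 5.0, 1.0, 1.0, 1.0])
        t1 = self._mini_traj(chain, stiff, stiff, inj)          # spring 1 bound
        t2 = self._mini_traj(chain, stiff, np.ones(5), inj)     # none bound
        pooled = fn.fibrotic_probability_by_cc([t1, t2], [10])
        solo1 = fn.fibrotic_probability_by_cc([t1], [10])
        solo2 = fn.fibrotic_probability_by_cc([t2], [10])
        for _, row in pooled.iterrows():
            n1 = solo1[solo1["cc"] == row["cc"]]["n_total"].sum()
            n2 = solo2[solo2["cc"] == row["cc"]]["n_total"].sum()
            assert row["n_total"] == n1 + n2
        assert np.all((pooled["probability"] >= 0) & (pooled["probability"] <= 1))

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            fn.fibrotic_probability_by_cc([], [10])


class TestClassifyOutcome:
    def test_monotone_return_is_healed(self, tiny_net):
        K0 = tiny_net.n_springs * tiny_net.k0
        traj = synthetic_trajectory(tiny_net, q=0.02, K0=K0, Ki=2 * K0)
        assert fn.classify_outcome(traj).label == HEALED

    def test_divergence_is_fibrotic(self, tiny_net):
        K0 = tiny_net.n_springs * tiny_net.k0
        traj = synthetic_trajectory(tiny_net, q=-0.004, K0=K0, Ki=1.05 * K0)
        assert fn.classify_outcome(traj).label == FIBROTIC

    def test_label_matches_sign_of_q_on_closed_form(self, tiny_net, rng):
        K0 = tiny_net.n_springs * tiny_net.k0
        for _ in range(20):
            q = rng.choice([-1.0, 1.0]) * rng.uniform(0.005, 0.02)
            traj = synthetic_trajectory(tiny_net, q=q, K0=K0, Ki=1.6 * K0)
            label = fn.classify_outcome(traj).label
            assert label == (HEALED if q > 0 else FIBROTIC)
            fit = fn.fit_reduced_model(traj)
            assert fit.classification == label

    def test_truncated_rejected(self, tiny_net):
        traj = synthetic_trajectory(tiny_net, q=0.01, K0=10.0, Ki=20.0, n=4)
        with pytest.raises(InvalidStateError):
            fn.classify_outcome(traj)


class TestFindCriticalCsa:
    def test_same_outcome_returns_none(self):
        assert fn.find_critical_csa(lambda v: HEALED, 1.0, 5.0) is None

    def test_step_oracle_recovery_50_locations(self, rng):
        """Bisection recovers 50 random step locations within tolerance."""
        for _ in range(50):
            step = rng.uniform(1.05, 4.95)
            oracle = lambda v, s=step: FIBROTIC if v >= s else HEALED
            found = fn.find_critical_csa(oracle, 1.0, 5.0, tolerance=0.05)
            assert found == pytest.approx(step, abs=0.05)

    def test_bisection_call_budget(self):
        calls = []
        def oracle(v):
            calls.append(v)
            return FIBROTIC if v >= 4.3 else HEALED
        found = fn.find_critical_csa(oracle, 1.0, 5.0, tolerance=0.1)
        assert found == pytest.approx(4.3, abs=0.1)
        assert len(calls) <= 2 + 6  # endpoints + ceil(log2(4 / 0.1))

    def test_sweep_list_input(self):
        sweep = [(1.0, HEALED, None), (2.0, HEALED, None), (3.0, FIBROTIC, None)]
        assert fn.find_critical_csa(sweep) == pytest.approx(2.5)

    def test_non_monotone_sweep_warns(self):
        sweep = [
            (1.0, HEALED, None), (2.0, FIBROTIC, None),
            (3.0, HEALED, None), (4.0, FIBROTIC, None),
        ]
        with pytest.warns(UserWarning):
            found = fn.find_critical_csa(sweep)
        assert found == pytest.approx(1.5)


class TestCompareOutcomeGeometry:
    def _reports(self, net, seeds):
        reps = []
        for s in seeds:
            pat = fn.random_injury(net, 0.2, 5.0, rng_seed=s)
            reps.append(fn.geometry_report(net, pat.spring_ids))
        return reps

    def test_identical_samples(self, tiny_net):
        reps = self._reports(tiny_net, range(5))
        table = fn.compare_outcome_geometry(reps, reps)
        assert np.all(table["ks_statistic"] == 0)
        assert np.all(table["p_value"] == 1)

    def test_disjoint_supports(self, tiny_net):
        reps_a = self._reports(tiny_net, range(5))
        reps_b = self._reports(tiny_net, range(5))
        # shift group b's coordinates far away via a scaled copy
        shifted = []
        for s in range(5, 10):
            pat = fn.random_injury(tiny_net, 0.2, 5.0, rng_seed=s)
            big = tiny_net.copy()
            big.positions = big.positions * 40.0
            big.rest_length = big.rest_length * 40.0
            shifted.append(fn.geometry_report(big, pat.spring_ids))
        table = fn.compare_outcome_geometry(reps_a, shifted)
        assert np.all(table["p_value"] < 1e-6)

    def test_empty_group_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            fn.compare_outcome_geometry([], self._reports(tiny_net, [1]))


class TestPercolation:
    def test_extreme_occupation(self, raw_net):
        from fibronet.analysis import _spans

        assert _spans(raw_net, np.ones(raw_net.n_springs, bool))
        assert not _spans(raw_net, np.zeros(raw_net.n_springs, bool))

    def test_monotone_spanning_probability(self, raw_net):
        est = fn.estimate_percolation_threshold(
            raw_net,
            p_grid=[0.45, 0.55, 0.65, 0.75, 0.85],
            replicates=60,
            rng_seed=4,
        )
        noise = 3 * np.sqrt(0.25 / 60)
        assert np.all(np.diff(est.spanning_probability) > -noise)
        assert 0.45 < est.threshold < 0.85

    def test_threshold_in_band_small_scale(self):
        """Desk-scale check: 2D Voronoi bond threshold lands in [0.62, 0.72]."""
        nets = [
            fn.generate_voronoi_network(
                600, rng_seed=s, lloyd_iterations=0, min_edge_frac=0.0
            )
            for s in (0, 1)
        ]
        est = fn.estimate_percolation_threshold(nets, replicates=100, rng_seed=9)
        assert 0.62 <= est.threshold <= 0.72

    def test_no_crossing_raises(self, raw_net):
        with pytest.raises(NoCrossingError):
            fn.estimate_percolation_threshold(
                raw_net, p_grid=[0.9, 0.95], replicates=20, rng_seed=1
            )


class TestReducedModel:
    def test_initial_and_asymptotic_values(self):
        assert fn.reduced_model_solution(7.0, 3.0, 0.5, 0.0) == pytest.approx(7.0)
        assert fn.reduced_model_solution(7.0, 3.0, 0.5, 1e6) == pytest.approx(3.0)

    @pytest.mark.parametrize("q", [0.01, -0.003, 0.2])
    def test_matches_runge_kutta_oracle(self, q):
        Ki, K0 = 250.0, 200.0
        t = np.linspace(0.0, 300.0, 120)
        ours = fn.reduced_model_solution(Ki, K0, q, t)
        sol = solve_ivp(
            lambda _, k: -q * (k - K0), (0.0, 300.0), [Ki],
            t_eval=t, rtol=1e-11, atol=1e-12,
        )
        assert np.allclose(ours, sol.y[0], rtol=1e-8, atol=1e-8)

    def test_noise_free_recovery(self, tiny_net):
        K0 = tiny_net.n_springs * tiny_net.k0
        traj = synthetic_trajectory(tiny_net, q=0.01, K0=K0, Ki=1.8 * K0)
        fit = fn.fit_reduced_model(traj)
        assert fit.q == pytest.approx(0.01, abs=1e-6)
        assert fit.Ki == pytest.approx(1.8 * K0, rel=1e-4)

    def test_q_recovery_under_noise_100_trajectories(self, tiny_net):
        """Within 10% relative error at noise SD = 2% of K0."""
        K0 = tiny_net.n_springs * tiny_net.k0
        rng = np.random.default_rng(7)
        for _ in range(100):
            q = rng.choice([-1, 1]) * rng.uniform(0.004, 0.02)
            traj = synthetic_trajectory(
                tiny_net, q=q, K0=K0, Ki=1.8 * K0, n=600,
                noise=0.02 * K0, rng=rng,
            )
            fit = fn.fit_reduced_model(traj)
            assert fit.q == pytest.approx(q, rel=0.10)

    def test_negative_q_classified_fibrotic(self, tiny_net):
        K0 = tiny_net.n_springs * tiny_net.k0
        rng = np.random.default_rng(3)
        traj = synthetic_trajectory(
            tiny_net, q=-0.005, K0=K0, Ki=1.1 * K0, noise=0.002 * K0, rng=rng
        )
        fit = fn.fit_reduced_model(traj)
        assert fit.q < 0 and fit.classification == FIBROTIC

    def test_constant_trajectory_unidentifiable(self, tiny_net):
        K0 = tiny_net.n_springs * tiny_net.k0
        traj = synthetic_trajectory(tiny_net, q=0.01, K0=K0, Ki=K0)
        fit = fn.fit_reduced_model(traj)
        assert fit.unidentifiable
        assert fit.classification is None


class TestHotspotSweep:
    def test_identity_value_reproduces_base_run(self, tiny_net, params):
        inj = fn.clustered_injury(tiny_net, 8, seed_spring=3, rng_seed=2)
        base = fn.run_simulation(
            tiny_net, inj, n_iterations=80, injury_iteration=40,
            params=params, rng_seed=5,
        )
        results = fn.hotspot_sweep(
            tiny_net, inj, 3, [5.0], run_seed=5,
            n_iterations=80, injury_iteration=40, params=params,
            classify_kwargs={"trend_window": 0.5},
        )
        (value, _, traj), = results
        assert value == 5.0
        assert np.array_equal(traj.total_stiffness, base.total_stiffness)

    def test_spring_outside_injury_rejected(self, tiny_net):
        inj = fn.clustered_injury(tiny_net, 8, seed_spring=3, rng_seed=2)
        outside = next(
            j for j in range(tiny_net.n_springs) if j not in inj.spring_ids
        )
        with pytest.raises(ValueError):
            fn.hotspot_sweep(tiny_net, inj, outside, [1.0, 5.0])
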