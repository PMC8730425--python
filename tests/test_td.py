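"""Shaped TD(0): the prediction error, online updates, traces, equivalences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdshaping import (
    TERMINAL,
    PotentialFunction,
    TDConfig,
    Trajectory,
    average_traces,
    generate_random_problem,
    perfect_shaping,
    run_averaged_experiment,
    run_experiment,
    run_trial,
    sample_trajectory,
    shaping_as_initialization,
    solve_values,
    td_error,
)


class TestTdError:
    @pytest.mark.parametrize(
        "reward, phi_from, phi_to, v_from, v_to, expected",
        [
            # unit terminal reward, no shaping, blank values
            (1.0, 0.0, 0.0, 0.0, 0.0, 1.0),
            # perfectly shaped interior chain step: flat potential cancels
            (0.0, 1.0, 1.0, 0.0, 0.0, 0.0),
            # perfectly shaped final chain step: reward offsets the potential drop
            (1.0, 1.0, 0.0, 0.0, 0.0, 0.0),
            # converged unshaped chain, branch taken: positive surprise
            (0.0, 0.0, 0.0, 0.3, 1.0, 0.7),
            # converged unshaped chain, branch missed: negative surprise
            (0.0, 0.0, 0.0, 0.3, 0.0, -0.3),
        ],
    )
    def test_shaped_error_values(self, reward, phi_from, phi_to, v_from, v_to, expected):
        assert td_error(reward, phi_from, phi_to, v_from, v_to) == pytest.approx(expected)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        phis=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=2,
            max_size=8,
        )
    )
    def test_potential_differences_cancel_around_cycles(self, phis):
        """The net shaping contribution around any ordered cycle is zero
        (the no-curl property that makes phi a potential)."""
        diffs = [phis[(i + 1) % len(phis)] - phis[i] for i in range(len(phis))]
        assert abs(sum(diffs)) < 1e-9


class TestRunTrial:
    def test_single_transition_update(self):
        traj = Trajectory(states=(0, TERMINAL), rewards=(1.0,))
        values, deltas = run_trial(
            np.zeros(1), traj, PotentialFunction.zeros(1), alpha=0.1
        )
        assert values[0] == pytest.approx(0.1)
        np.testing.assert_array_equal(deltas, [1.0])

    def test_perfectly_shaped_chain_is_silent_after_first_step(self, ideal_phi):
        states = tuple(range(11)) + (TERMINAL,)
        rewards = (0.0,) * 9 + (1.0, 0.0)
        values, deltas = run_trial(
            np.zeros(11), Trajectory(states, rewards), ideal_phi, alpha=0.1
        )
        np.testing.assert_array_equal(deltas[1:], np.zeros(10))
        assert deltas[0] == pytest.approx(1.0)
        # nothing to learn between ingestion and digestion
        np.testing.assert_array_equal(values[1:], np.zeros(10))
        assert values[0] == pytest.approx(0.1)

    def test_converged_values_are_a_fixed_point(self):
        """On a deterministic chain at the exact values, every delta is zero
        and the values are untouched."""
        from tdshaping import ChainSpec, build_chain

        problem = build_chain(ChainSpec(p=1.0, T=5, reward_schedule={5: 1.0}))
        exact = solve_values(problem)
        traj = sample_trajectory(problem, 0, np.random.default_rng(0))
        values, deltas = run_trial(
            exact, traj, PotentialFunction.zeros(6), alpha=0.5
        )
        np.testing.assert_allclose(deltas, np.zeros(6), atol=1e-12)
        np.testing.assert_allclose(values, exact, atol=1e-12)


class TestRunExperiment:
    def test_matches_sample_then_learn(self, fig1_problem, ideal_phi):
        """The fused experiment loop is step-for-step identical to sampling a
        trajectory and then applying run_trial, on the same random stream."""
        cfg = TDConfig(alpha=0.1, n_trials=200, seed=13)
        trace = run_experiment(fig1_problem, ideal_phi, cfg)
        rng = np.random.default_rng(cfg.seed)
        values = np.zeros(11)
        for k in range(cfg.n_trials):
            traj = sample_trajectory(fig1_problem, 0, rng)
            values, deltas = run_trial(values, traj, ideal_phi, cfg.alpha)
            np.testing.assert_array_equal(trace.values_by_trial[k], values)
            np.testing.assert_array_equal(trace.deltas_by_trial[k].deltas, deltas)
            assert tuple(trace.deltas_by_trial[k].from_states) == traj.states[:-1]

    def test_bit_identical_given_seed(self, fig1_problem, zero_phi):
        cfg = TDConfig(alpha=0.1, n_trials=300, seed=99)
        a = run_experiment(fig1_problem, zero_phi, cfg)
        b = run_experiment(fig1_problem, zero_phi, cfg)
        np.testing.assert_array_equal(a.values_by_trial, b.values_by_trial)
        for da, db in zip(a.deltas_by_trial, b.deltas_by_trial):
            np.testing.assert_array_equal(da.deltas, db.deltas)
            np.testing.assert_array_equal(da.from_states, db.from_states)
            np.testing.assert_array_equal(da.to_states, db.to_states)

    def test_single_trial_returns_single_snapshot(self, fig1_problem, zero_phi):
        trace = run_experiment(
            fig1_problem, zero_phi, TDConfig(alpha=0.1, n_trials=1, seed=0)
        )
        assert trace.values_by_trial.shape == (1, 11)
        assert len(trace.deltas_by_trial) == 1

    def test_zero_trials_disallowed(self):
        with pytest.raises(ValueError):
            TDConfig(alpha=0.1, n_trials=0)

    def test_alpha_bounds_enforced(self):
        with pytest.raises(ValueError):
            TDConfig(alpha=0.0, n_trials=10)
        with pytest.raises(ValueError):
            TDConfig(alpha=1.5, n_trials=10)


class TestInitializationEquivalence:
    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_shaping_equals_initialising_at_phi(self, seed):
        """Learning with potential phi from zero values tracks unshaped
        learning initialised at phi: V_shaped + phi = V_init after every
        episode, on identical trajectory streams."""
        rng_p = np.random.default_rng(seed)
        problem = generate_random_problem(4, seed=seed)
        phi = PotentialFunction(rng_p.uniform(-2, 2, 4))
        cfg = TDConfig(alpha=0.3, n_trials=40, seed=seed + 1)
        shaped = run_experiment(problem, phi, cfg)
        init_cfg = shaping_as_initialization(problem, phi, cfg)
        plain = run_experiment(problem, PotentialFunction.zeros(4), init_cfg)
        np.testing.assert_allclose(
            shaped.values_by_trial + phi.phi,
            plain.values_by_trial,
            atol=1e-10,
        )

    def test_zero_potential_leaves_config_unchanged(self, fig1_problem):
        cfg = TDConfig(alpha=0.1, n_trials=5, seed=0)
        assert shaping_as_initialization(
            fig1_problem, PotentialFunction.zeros(11), cfg
        ) is cfg

    def test_ideal_potential_becomes_initial_values(self, fig1_problem, ideal_phi):
        cfg = shaping_as_initialization(
            fig1_problem, ideal_phi, TDConfig(alpha=0.1, n_trials=5)
        )
        np.testing.assert_array_equal(
            cfg.initial_values, [0.0] + [1.0] * 9 + [0.0]
        )


class TestAveraging:
    def test_average_with_itself_is_identity(self, fig1_problem, zero_phi):
        trace = run_experiment(
            fig1_problem, zero_phi, TDConfig(alpha=0.1, n_trials=50, seed=2)
        )
        avg = average_traces([trace, trace])
        np.testing.assert_allclose(avg.values_by_trial, trace.values_by_trial, atol=1e-12)
        np.testing.assert_allclose(
            avg.delta_matrix(), trace.delta_matrix(), atol=1e-12, equal_nan=True
        )
        assert avg.n_runs == 2

    def test_mismatched_shapes_rejected(self, fig1_problem, zero_phi):
        a = run_experiment(fig1_problem, zero_phi, TDConfig(alpha=0.1, n_trials=10, seed=0))
        b = run_experiment(fig1_problem, zero_phi, TDConfig(alpha=0.1, n_trials=20, seed=0))
        with pytest.raises(ValueError):
            average_traces([a, b])

    def test_asymptotic_compensation_on_random_problem(self):
        """Across-run mean of V + phi approaches the exact values: an
        imperfect potential is exactly paid back by learning."""
        problem = generate_random_problem(3, seed=31, max_reward=1.0)
        phi = PotentialFunction(np.array([0.5, -1.0, 2.0]))
        avg = run_averaged_experiment(
            problem,
            phi,
            TDConfig(alpha=0.05, n_trials=3000, seed=100),
            n_runs=100,
        )
        exact = solve_values(problem)
        assert np.max(np.abs(avg.final_values + phi.phi - exact)) < 0.05


class TestTraceExport:
    def test_values_and_deltas_frames_round_trip(self, fig1_problem, zero_phi):
        trace = run_experiment(
            fig1_problem, zero_phi, TDConfig(alpha=0.1, n_trials=20, seed=5)
        )
        vf = trace.to_values_frame()
        assert set(vf.columns) == {"trial", "state_label", "value"}
        rebuilt = vf.pivot(index="trial", columns="state_label", values="value")
        rebuilt = rebuilt[list(trace.labels)].to_numpy()
        np.testing.assert_array_equal(rebuilt, trace.values_by_trial)
        df = trace.to_deltas_frame()
        assert set(df.columns) == {"trial", "step", "from_state", "to_state", "delta"}
        for k, d in enumerate(trace.deltas_by_trial, start=1):
            np.testing.assert_array_equal(
                df.loc[df["trial"] == k, "delta"].to_numpy(), d.deltas
            )
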