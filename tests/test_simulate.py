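"""Simulation engines against closed-form and statistical oracles."""

import numpy as np
import pytest

from gemkin.network import NetworkModel, Reaction, Species, scale_model
from gemkin.simulate import (
    SimConfig,
    Trajectory,
    auc,
    mean_trajectory,
    ode_simulate,
    ssa_auc,
    ssa_simulate,
)
from gemkin.synthetic import make_toy_chain


def decay_model(k=1.0):
    return NetworkModel([Species("A")], [Reaction("decay", (("A", 1),), (), k)])


def birth_death_model(birth=40.0, death=0.5):
    return NetworkModel(
        [Species("A")],
        [
            Reaction("birth", (), (("A", 1),), birth),
            Reaction("death", (("A", 1),), (), death),
        ],
    )


class TestSSA:
    def test_zero_propensity_constant_trajectory(self):
        model = decay_model(0.0)
        traj = ssa_simulate(model, {"A": 7}, SimConfig(t_end=24.0, seed=3))
        assert traj.kind == "event"
        assert traj.times[-1] == 24.0
        assert np.all(traj.counts("A") == 7)

    def test_pure_decay_matches_exponential_law(self):
        # n(4h) is Binomial(1000, e^-4); compare the replicate mean
        # against the analytic survival probability within 3 SE
        k, n0, t, reps = 1.0, 1000, 4.0, 200
        model = decay_model(k)
        p = np.exp(-k * t)
        vals = [
            ssa_simulate(model, {"A": n0}, SimConfig(t_end=t, seed=s)).states[-1, 0]
            for s in range(reps)
        ]
        se = np.sqrt(n0 * p * (1 - p) / reps)
        assert abs(np.mean(vals) - n0 * p) < 3 * se

    def test_seed_determinism_byte_identical(self, toy_chain3):
        cfg = SimConfig(t_end=10.0, seed=42)
        a = ssa_simulate(toy_chain3, {"S0": 500}, cfg)
        b = ssa_simulate(toy_chain3, {"S0": 500}, cfg)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)

    def test_different_seeds_differ(self, toy_chain3):
        a = ssa_simulate(toy_chain3, {"S0": 500}, SimConfig(seed=1))
        b = ssa_simulate(toy_chain3, {"S0": 500}, SimConfig(seed=2))
        assert not np.array_equal(a.times, b.times)

    def test_no_negative_counts_ever(self, toy_chain3):
        traj = ssa_simulate(toy_chain3, {"S0": 300}, SimConfig(seed=5))
        assert np.all(traj.states >= 0)

    def test_chain_total_count_conserved(self, toy_chain3):
        traj = ssa_simulate(toy_chain3, {"S0": 300}, SimConfig(seed=6))
        totals = traj.states.sum(axis=1)
        assert np.all(totals == 300)

    def test_negative_initial_count_rejected(self, toy_chain3):
        with pytest.raises(ValueError):
            ssa_simulate(toy_chain3, {"S0": -1}, SimConfig())

    def test_event_buffer_growth_is_transparent(self):
        model = birth_death_model(birth=500.0, death=0.1)
        small = ssa_simulate(model, {"A": 0}, SimConfig(t_end=20.0, seed=9),
                             max_events=64)
        big = ssa_simulate(model, {"A": 0}, SimConfig(t_end=20.0, seed=9))
        assert np.array_equal(small.times, big.times)


@pytest.fixture(scope="module")
def scaled_run(calibrated_model, calibrated_state):
    # scaling 1e-4 keeps the event-resolved record small; the
    # conservation properties are scale-independent
    ms, ss = scale_model(calibrated_model, calibrated_state, 1e-4)
    return ssa_simulate(ms, ss, SimConfig(seed=11), max_events=4_000_000)


class TestGemcitabineTrajectories:

    def test_enzyme_moieties_exact_at_every_event(self, scaled_run):
        for pair in (("dCK", "dCK:dCTP"), ("RR", "RR:dFdC-DP"),
                     ("dCMPD", "dCMPD:dFdC-TP")):
            total = scaled_run.counts(pair[0]) + scaled_run.counts(pair[1])
            assert np.all(total == total[0]), pair

    def test_rr_complex_nondecreasing(self, scaled_run):
        rr = scaled_run.counts("RR:dFdC-DP")
        assert np.all(np.diff(rr) >= 0)

    def test_disabled_inhibition_complex_identically_zero(
        self, no_dcmpd_inhibition_config
    ):
        from gemkin.network import build_gemcitabine_network, initial_state

        model = build_gemcitabine_network(no_dcmpd_inhibition_config)
        state = initial_state(no_dcmpd_inhibition_config, dfdc_out=5e6,
                              endogenous={"dCTP": 215000})
        ms, ss = scale_model(model, state, 1e-4)
        traj = ssa_simulate(ms, ss, SimConfig(seed=2), max_events=4_000_000)
        assert np.all(traj.counts("dCMPD:dFdC-TP") == 0)


class TestODE:
    def test_single_transfer_closed_form(self):
        # A -> B, k=1/h, A(0)=100: A(1h) = 100 e^-1
        model = make_toy_chain(1, [1.0])
        traj = ode_simulate(model, {"S0": 100.0}, np.array([0.0, 1.0]))
        assert traj.counts("S0")[-1] == pytest.approx(100 * np.exp(-1), rel=1e-6)

    def test_empty_reaction_list_constant(self):
        model = NetworkModel([Species("A")], [])
        traj = ode_simulate(model, {"A": 5.0}, np.linspace(0, 10, 11))
        assert np.all(traj.counts("A") == 5.0)

    def test_birth_death_steady_state_flux_balance(self):
        # production k with loss c: steady state A = k/c
        model = birth_death_model(birth=40.0, death=0.5)
        traj = ode_simulate(model, {"A": 0.0}, np.array([0.0, 100.0]))
        assert traj.counts("A")[-1] == pytest.approx(80.0, rel=1e-6)

    def test_grid_must_increase_from_zero(self, toy_chain3):
        with pytest.raises(ValueError):
            ode_simulate(toy_chain3, {"S0": 1.0}, np.array([1.0, 2.0]))

    def test_ssa_mean_tracks_ode_at_large_counts(self, toy_chain3):
        # law of large numbers: relative fluctuations ~ 1/sqrt(n)
        state = {"S0": 100_000}
        grid = np.array([0.0, 2.0, 6.0])
        ode = ode_simulate(toy_chain3, state, grid)
        mean = mean_trajectory(
            toy_chain3, state, SimConfig(t_end=6.0, seed=7, replicates=4), grid
        )
        mask = ode.states[-1] > 500
        rel = np.abs(mean.states[-1, mask] / ode.states[-1, mask] - 1)
        assert np.max(rel) < 0.05


class TestMeanTrajectory:
    def test_single_replicate_is_resampled_run(self, toy_chain3):
        cfg = SimConfig(t_end=8.0, seed=21, replicates=1)
        grid = np.linspace(0, 8, 17)
        mean = mean_trajectory(toy_chain3, {"S0": 200}, cfg, grid)
        assert mean.kind == "grid"
        assert np.array_equal(mean.times, grid)
        # counts of a single resampled run remain integers
        assert np.allclose(mean.states, np.round(mean.states))

    def test_decay_mean_within_three_se_of_analytic(self):
        k, n0, reps = 0.5, 400, 500
        model = decay_model(k)
        grid = np.array([0.0, 1.0, 2.0, 4.0])
        mean = mean_trajectory(
            model, {"A": n0}, SimConfig(t_end=4.0, seed=13, replicates=reps), grid
        )
        for t, m in zip(grid[1:], mean.counts("A")[1:]):
            p = np.exp(-k * t)
            se = np.sqrt(n0 * p * (1 - p) / reps)
            assert abs(m - n0 * p) < 3 * se, t

    def test_conserved_total_independent_of_seed(self, toy_chain3):
        for seed in (1, 2):
            mean = mean_trajectory(
                toy_chain3, {"S0": 250}, SimConfig(seed=seed, replicates=3)
            )
            np.testing.assert_allclose(mean.states.sum(axis=1), 250)


class TestAUC:
    def test_constant_level_rectangle(self):
        traj = Trajectory(
            np.array([0.0, 24.0]), np.full((2, 1), 100.0), ["X"], "event"
        )
        assert auc(traj, "X", (0, 24)) == pytest.approx(2400)

    def test_two_step_path(self):
        # 10 on [0,2), 20 on [2,5): AUC over [0,5] = 20 + 60 = 80
        traj = Trajectory(
            np.array([0.0, 2.0, 5.0]),
            np.array([[10.0], [20.0], [20.0]]),
            ["X"],
            "event",
        )
        assert auc(traj, "X", (0, 5)) == pytest.approx(80)

    def test_additivity_over_adjacent_windows(self, toy_chain3):
        traj = ssa_simulate(toy_chain3, {"S0": 100}, SimConfig(t_end=12.0, seed=4))
        a = auc(traj, "S1", (0, 5))
        b = auc(traj, "S1", (5, 12))
        c = auc(traj, "S1", (0, 12))
        assert a + b == pytest.approx(c, rel=1e-12)

    def test_event_and_accumulated_auc_agree_exactly(self, toy_chain3):
        cfg = SimConfig(t_end=9.0, seed=17)
        traj = ssa_simulate(toy_chain3, {"S0": 400}, cfg)
        accumulated = ssa_auc(toy_chain3, {"S0": 400}, 9.0, seed=17)
        for sp in ("S0", "S1", "S2", "S3"):
            assert auc(traj, sp, (0, 9.0)) == pytest.approx(
                accumulated[sp], rel=1e-9
            )

    def test_ode_auc_scales_linearly_with_count_scaling(self, calibrated_model,
                                                        calibrated_state):
        s = 1e-2
        grid = np.linspace(0.0, 24.0, 49)
        full = ode_simulate(calibrated_model, calibrated_state, grid)
        ms, ss = scale_model(calibrated_model, calibrated_state, s)
        scaled = ode_simulate(ms, ss, grid)
        a_full = auc(full, "dFdC-TP", (0, 24))
        a_scaled = auc(scaled, "dFdC-TP", (0, 24))
        assert a_scaled == pytest.approx(s * a_full, rel=1e-3)

    def test_window_validation(self, toy_chain3):
        traj = ssa_simulate(toy_chain3, {"S0": 10}, SimConfig(t_end=5.0, seed=1))
        with pytest.raises(ValueError):
            auc(traj, "S0", (3, 3))
        with pytest.raises(ValueError):
            auc(traj, "S0", (0, 10))
        with pytest.raises(KeyError):
            auc(traj, "nope", (0, 5))
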