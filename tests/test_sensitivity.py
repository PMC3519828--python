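"""AUC sweeps, complementarity and efficacy-ratio statistics."""

import numpy as np
import pytest

from gemkin.network import scale_model
from gemkin.sensitivity import (
    AUCSurface,
    SweepGrid,
    complementarity_score,
    efficacy_factorial,
    efficacy_ratio,
    sweep_auc,
)
from gemkin.simulate import SimConfig, Trajectory, auc, replicate_seeds, ssa_auc
from gemkin.synthetic import make_toy_chain


def constant_traj(levels: dict[str, float], t_end=24.0):
    species = list(levels)
    states = np.tile(np.array([list(levels.values())]), (2, 1))
    return Trajectory(np.array([0.0, t_end]), states, species, "event")


class TestEfficacyRatio:
    def test_equal_levels_give_unity(self):
        traj = constant_traj({"dFdC-TP": 150.0, "dCTP": 150.0})
        assert efficacy_ratio(traj) == pytest.approx(1.0)

    def test_rectangle_ratio(self):
        traj = constant_traj({"dFdC-TP": 200.0, "dCTP": 100.0})
        assert efficacy_ratio(traj) == pytest.approx(2.0)

    def test_zero_dctp_exposure_is_undefined(self):
        traj = constant_traj({"dFdC-TP": 200.0, "dCTP": 0.0})
        assert np.isnan(efficacy_ratio(traj))


class TestComplementarityScore:
    def surface(self, a, b):
        grid = SweepGrid(axes={"bind_dCK": np.arange(1, len(a) + 1, dtype=float)})
        return AUCSurface(grid, {"dFdC-TP": np.asarray(a, float),
                                 "dCTP": np.asarray(b, float)})

    def test_perfect_anti_monotonicity(self):
        a = [5.0, 1.0, 4.0, 2.0]
        b = [-x for x in a]
        assert complementarity_score(self.surface(a, b)) == pytest.approx(-1.0)

    def test_identical_arrays(self):
        a = [1.0, 3.0, 2.0, 5.0]
        assert complementarity_score(self.surface(a, a)) == pytest.approx(1.0)

    def test_constant_array_is_undefined(self):
        assert np.isnan(
            complementarity_score(self.surface([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        )


class TestSweepAUC:
    def test_degenerate_grid_equals_control_run(self, calibrated_model,
                                                calibrated_state):
        control = calibrated_model.rate("bind_dCK")
        grid = SweepGrid(
            axes={"bind_dCK": np.array([control])},
            scaling=1e-3,
            replicates=3,
            seed=5,
        )
        surface = sweep_auc(calibrated_model, calibrated_state, grid)
        ms, ss = scale_model(calibrated_model, calibrated_state, 1e-3)
        seeds = replicate_seeds(5, 3)
        expected = np.mean(
            [ssa_auc(ms, ss, 24.0, int(s))["dFdC-TP"] for s in seeds]
        ) / 1e-3
        assert surface.values["dFdC-TP"][0] == pytest.approx(expected, rel=1e-12)

    def test_absent_parameter_rejected(self, toy_chain3):
        grid = SweepGrid(axes={"not_a_reaction": np.array([1.0])})
        with pytest.raises(KeyError):
            sweep_auc(toy_chain3, {"S0": 100}, grid, species=("S1",))

    def test_flat_surface_when_parameter_never_enters_propensities(self):
        # swept reaction consumes a species that stays at zero copies, so
        # its propensity is identically 0 and every sample path is the
        # same regardless of the swept value: the surface is exactly flat
        from gemkin.network import NetworkModel, Reaction, Species

        model = NetworkModel(
            [Species(n) for n in ("S0", "S1", "X", "Y")],
            [
                Reaction("step_0", (("S0", 1),), (("S1", 1),), 0.5),
                Reaction("orphan", (("X", 1),), (("Y", 1),), 1.0),
            ],
        )
        grid = SweepGrid(
            axes={"orphan": np.geomspace(1e-3, 1.0, 4)},
            scaling=1.0,
            replicates=2,
            seed=7,
        )
        surface = sweep_auc(model, {"S0": 200}, grid, species=("S1",))
        vals = surface.values["S1"]
        assert np.all(vals == vals[0])

    def test_surface_reproducible_given_seed(self, calibrated_model,
                                             calibrated_state):
        grid = dict(axes={"bind_dCK": np.array([1e-6, 1e-4])},
                    scaling=1e-3, replicates=2, seed=9)
        s1 = sweep_auc(calibrated_model, calibrated_state, SweepGrid(**grid))
        s2 = sweep_auc(calibrated_model, calibrated_state, SweepGrid(**grid))
        for sp in s1.values:
            np.testing.assert_array_equal(s1.values[sp], s2.values[sp])

    def test_long_format_export(self, calibrated_model, calibrated_state,
                                tmp_path):
        grid = SweepGrid(axes={"bind_dCK": np.array([1e-6, 1e-5])},
                         scaling=1e-3, replicates=2, seed=1)
        surface = sweep_auc(calibrated_model, calibrated_state, grid)
        df = surface.to_frame()
        assert set(df.columns) == {"bind_dCK", "species", "auc", "sem"}
        assert len(df) == 4  # 2 grid points x 2 species
        surface.to_csv(tmp_path / "sweep.csv")
        assert (tmp_path / "sweep.csv").exists()


class TestComplementarityBand:
    def test_anticoupling_strongest_near_control_rr_association(
        self, calibrated_model, calibrated_state
    ):
        # the complementary regime needs RR binding fast enough to react
        # to the dFdC-DP produced under permissive dCK conditions but not
        # so fast that dCTP dies for every condition; around the control
        # association rate the dCK sweep shows strong anti-coupling
        from gemkin.sensitivity import control_association_axis

        dck_axis = control_association_axis(calibrated_model, "bind_dCK", n=6)
        rr_band = 4 * calibrated_model.rate("bind_RR")

        def score(rr):
            grid = SweepGrid(axes={"bind_dCK": dck_axis},
                             fixed={"bind_RR": rr}, scaling=1e-3,
                             replicates=10, seed=202, equilibrate=True)
            return complementarity_score(
                sweep_auc(calibrated_model, calibrated_state, grid)
            )

        assert score(rr_band) < -0.5
        assert abs(score(0.0)) < 0.5


class TestScalingSanity:
    def test_surfaces_rank_consistent_across_scalings(self, calibrated_model,
                                                      calibrated_state):
        # smaller scaling amplifies intrinsic noise but must preserve the
        # ordering of grid points for the dFdC-TP exposure
        from scipy.stats import spearmanr

        from gemkin.sensitivity import control_association_axis

        axis = control_association_axis(calibrated_model, "bind_dCK", n=6)
        surfaces = []
        for scaling in (1e-3, 1e-4):
            grid = SweepGrid(axes={"bind_dCK": axis}, scaling=scaling,
                             replicates=10, seed=31, equilibrate=True)
            surfaces.append(
                sweep_auc(calibrated_model, calibrated_state, grid,
                          species=("dFdC-TP",)).values["dFdC-TP"]
            )
        rho = spearmanr(surfaces[0], surfaces[1]).statistic
        assert rho > 0.9, (rho, surfaces)


class TestZeroInflux:
    def test_no_drug_enters_no_triphosphate_exposure(self, calibrated_model,
                                                     calibrated_state):
        model = calibrated_model.with_rates({"influx_dFdC": 0.0})
        ms, ss = scale_model(model, calibrated_state, 1e-3)
        res = ssa_auc(ms, ss, 24.0, seed=3)
        assert res["dFdC-TP"] == 0.0
        assert res["dCTP"] > 0.0


class TestInfluxExperiment:
    def test_three_axis_surface_shape(self, calibrated_model, calibrated_state):
        from gemkin.sensitivity import influx_experiment

        control = calibrated_model.rate("influx_dFdC")
        surf = influx_experiment(
            calibrated_model, calibrated_state,
            influx_values=np.array([control, 10 * control]),
            dck_assoc_values=np.array([calibrated_model.rate("bind_dCK")]),
            rr_assoc_values=np.array([calibrated_model.rate("bind_RR")]),
            scaling=1e-4, replicates=2, seed=6,
        )
        assert surf.values["dFdC-TP"].shape == (2, 1, 1)
        assert np.all(surf.values["dFdC-TP"] > 0)


class TestEfficacyFactorial:
    def test_records_cover_grid_and_carry_ratio(self, calibrated_model,
                                                calibrated_state):
        recs = efficacy_factorial(
            calibrated_model, calibrated_state,
            dck_amounts=np.array([5e4, 2e5]),
            rr_amounts=np.array([1e5]),
            scaling=1e-3, replicates=2, seed=4,
        )
        assert len(recs) == 2
        assert recs[0].ratio == pytest.approx(0.5)
        assert recs[1].ratio == pytest.approx(2.0)
        assert all(np.isfinite(r.efficacy) for r in recs)
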