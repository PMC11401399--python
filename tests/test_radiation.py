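"""LQ survival, dose geometry, scheduling, and fraction application."""

import math

import numpy as np
import pytest

from gridabm import _kernel
from gridabm.dynamics import SimulationState
from gridabm.radiation import (DoseMap, GridGeometry, RadiosensitivityParams,
                               apply_fraction, build_grid_dose_map,
                               calibrate_lq, make_schedule, mean_dose,
                               monte_carlo_survival, survival_probability,
                               uniform_dose_map)


class TestCalibrateLq:
    def test_cancer_calibration_solves_linear_system(self):
        alpha, beta = calibrate_lq(0.49, 10.0)
        assert beta == pytest.approx(-math.log(0.49) / 24.0)  # 0.029722...
        assert alpha == pytest.approx(10.0 * beta)
        assert math.exp(-(2 * alpha + 4 * beta)) == pytest.approx(0.49, abs=1e-9)

    def test_unity_survival_gives_zero_sensitivity(self):
        assert calibrate_lq(1.0, 10.0) == (0.0, 0.0)

    @pytest.mark.parametrize("sf", [1.2, 0.0, -0.1])
    def test_invalid_survival_rejected(self, sf):
        with pytest.raises(ValueError):
            calibrate_lq(sf, 10.0)

    def test_all_classes_reproduce_their_2gy_targets(self, radio):
        for klass, sf2 in [("cancer", 0.49), ("effector", 0.60),
                           ("regulatory", 0.77)]:
            assert survival_probability(2.0, radio, klass) == \
                pytest.approx(sf2, abs=1e-9)


class TestSurvivalProbability:
    def test_zero_dose_is_certain_survival(self, radio):
        assert survival_probability(0.0, radio, "C") == 1.0

    def test_quiescent_equals_third_dose(self, radio):
        q = survival_probability(2.0, radio, "C", cycling=False)
        assert q == pytest.approx(survival_probability(2.0 / 3.0, radio, "C"))
        assert q > survival_probability(2.0, radio, "C")

    def test_quiescent_always_survives_more(self, radio):
        for d in np.linspace(0.1, 20, 25):
            assert survival_probability(d, radio, "C", cycling=False) > \
                survival_probability(d, radio, "C", cycling=True)

    def test_negative_dose_rejected(self, radio):
        with pytest.raises(ValueError):
            survival_probability(-1.0, radio, "C")


class TestGridGeometry:
    def test_two_dose_levels_only(self):
        dm = build_grid_dose_map(GridGeometry(), 2.0)
        assert set(np.round(np.unique(dm.values), 12)) == {0.3, 2.0}

    def test_single_interior_opening_covers_97_nodes(self):
        # offset by 0.5 so one opening center sits exactly on node (34, 25);
        # spacing 60 keeps every other opening outside the domain
        geom = GridGeometry(11.0, 60.0, offset=(0.5, 0.0))
        dm = build_grid_dose_map(geom, 2.0)
        brute = sum(1 for dx in range(-6, 7) for dy in range(-6, 7)
                    if dx * dx + dy * dy <= 5.5 ** 2)
        assert int((dm.values == 2.0).sum()) == brute == 97

    def test_unit_valley_fraction_degenerates_to_wtrt(self):
        geom = GridGeometry(11.0, 30.0, valley_fraction=1.0)
        dm = build_grid_dose_map(geom, 2.0)
        assert np.array_equal(dm.values, uniform_dose_map(2.0).values)

    def test_translation_invariance_by_one_period(self):
        a = build_grid_dose_map(GridGeometry(), 2.0)
        b = build_grid_dose_map(GridGeometry(offset=(30.0, 0.0)), 2.0)
        c = build_grid_dose_map(GridGeometry(offset=(0.0, 30.0)), 2.0)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.values, c.values)

    def test_merging_openings_rejected(self):
        with pytest.raises(ValueError):
            GridGeometry(opening_diameter=30.0, center_spacing=30.0)

    def test_matched_geometries_hit_stated_open_fractions(self):
        g30 = make_schedule("grid30").fractions[0][1]
        g50 = make_schedule("grid50").fractions[0][1]
        assert g30.open_fraction() == pytest.approx(0.30, abs=0.005)
        assert g50.open_fraction() == pytest.approx(0.50, abs=0.005)

    def test_csv_roundtrip(self, tmp_path):
        dm = build_grid_dose_map(GridGeometry(), 2.0)
        dm.to_csv(tmp_path / "dm.csv")
        back = DoseMap.from_csv(tmp_path / "dm.csv")
        assert np.allclose(back.values, dm.values)


class TestMeanDose:
    @pytest.mark.parametrize("f,expected", [
        (0.30, 0.81), (0.50, 1.15), (1.0, 2.0)])
    def test_printed_mean_doses(self, f, expected):
        assert mean_dose(f, 2.0, 0.15) == pytest.approx(expected)

    def test_formula_matches_direct_map_average(self):
        for kind in ("grid30", "grid50"):
            dm = make_schedule(kind).fractions[0][1]
            assert mean_dose(dm.open_fraction(), 2.0, 0.15) == \
                pytest.approx(dm.mean(), abs=1e-12)


class TestSchedule:
    def test_seven_weekday_weeks_deliver_70_gy(self):
        sched = make_schedule("wtrt", weeks=7, peak_dose=2.0)
        assert sched.n_fractions == 35
        assert sched.total_dose == pytest.approx(70.0)
        for h, _ in sched.fractions:
            assert (h % 168) // 24 < 5  # Mon-Fri only

    def test_one_week_has_five_fractions(self):
        assert make_schedule("wtrt", weeks=1).n_fractions == 5

    def test_single_ablative_custom_fraction(self):
        sched = make_schedule("custom", custom=[(0, 15.0)])
        assert sched.n_fractions == 1
        assert sched.fractions[0][1].peak_dose == 15.0

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            make_schedule("wtrt", peak_dose=-2.0)

    def test_schedule_export(self, tmp_path):
        make_schedule("wtrt", weeks=1).to_tsv(tmp_path / "s.tsv")
        lines = (tmp_path / "s.tsv").read_text().strip().splitlines()
        assert len(lines) == 6 and lines[0].startswith("hour")


class TestApplyFraction:
    def test_certain_survivors_lengthen_cycle_by_2h_per_gy(self, rng):
        params = RadiosensitivityParams(sf2_cancer=1.0)  # alpha = beta = 0
        state = SimulationState()
        c = state.add_agent("cancer", 5, 5, div_length=24.0)
        apply_fraction(state, uniform_dose_map(2.0), params, rng)
        assert state.div_length[c] == pytest.approx(28.0)
        assert not state.doomed[c]

    def test_quiescent_survivors_keep_cycle_length(self, rng):
        params = RadiosensitivityParams(sf2_cancer=1.0)
        state = SimulationState()
        c = state.add_agent("cancer", 5, 5, div_length=24.0)
        state.quiescent[c] = True
        apply_fraction(state, uniform_dose_map(2.0), params, rng)
        assert state.div_length[c] == 24.0

    def test_kill_is_delayed_by_8_hours(self, rng, cycle):
        from gridabm.dynamics import MotionParams, step_cancer
        params = RadiosensitivityParams(sf2_cancer=1e-12)  # certain kill
        state = SimulationState()
        state.seed_kernel(4)
        c = state.add_agent("cancer", 5, 5, div_length=1e9)
        state.hour = 10
        apply_fraction(state, uniform_dose_map(2.0), params, rng)
        assert state.doomed[c]
        assert state.death_hour[c] == 18.0
        state.reset_step_counters()
        step_cancer(state, c, MotionParams(p_a=0.0), cycle)
        assert state.kind[c] == _kernel.CANCER  # still occupies its node
        state.hour = 18
        step_cancer(state, c, MotionParams(p_a=0.0), cycle)
        assert state.kind[c] == _kernel.EMPTY
        assert state.read_step_deaths().c_tx == 1

    def test_monte_carlo_matches_closed_form(self, radio):
        n = 20000
        for klass, cycling, d in [("cancer", True, 2.0),
                                  ("cancer", False, 2.0),
                                  ("effector", True, 4.0)]:
            sf = survival_probability(d, radio, klass,
                                      cycling=cycling if klass == "cancer" else True)
            got = monte_carlo_survival(n, d, radio, klass, cycling=cycling,
                                       seed=42)
            se = math.sqrt(sf * (1 - sf) / n)
            assert abs(got - sf) < 4 * se
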