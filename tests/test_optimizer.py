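"""Robust optimizer: scenario generation, worst-case composites, plan
quality on water-box and pelvic phantoms."""
from __future__ import annotations

import numpy as np
import pytest

from adaptrt import (BeamModel, DoseGrid, PlanningGoals, RobustSetting,
                     Scenario, StructureSet, VoxelGrid, build_scenarios,
                     compute_dose, compute_dvh, dose_max, dvh_index_d,
                     optimize_spot_weights, worst_case_dose)
from adaptrt.trial import COHORT_BEAM


class TestBuildScenarios:
    def test_default_is_nine_scenarios(self):
        sc = build_scenarios(RobustSetting())
        assert len(sc) == 9
        nominal = [s for s in sc if s.is_nominal]
        assert len(nominal) == 1

    def test_shifts_have_3mm_linf_norm(self):
        sc = build_scenarios(RobustSetting(setup_mm=3.0))
        shifts = [s for s in sc if np.any(s.shift_mm)]
        assert len(shifts) == 6
        for s in shifts:
            assert np.abs(s.shift_mm).max() == pytest.approx(3.0)
            assert np.count_nonzero(s.shift_mm) == 1
            assert s.range_scale == 1.0

    def test_range_scales_not_crossed_with_shifts(self):
        sc = build_scenarios(RobustSetting(range_pct=3.5))
        scaled = [s for s in sc if s.range_scale != 1.0]
        assert sorted(s.range_scale for s in scaled) == [0.965, 1.035]
        for s in scaled:
            assert not np.any(s.shift_mm)

    def test_degenerate_setting_gives_nominal_only(self):
        sc = build_scenarios(RobustSetting(setup_mm=0.0, range_pct=0.0))
        assert len(sc) == 1 and sc[0].is_nominal


class TestWorstCase:
    def _doses(self, arrays):
        g = VoxelGrid((0, 0, 0), (1, 1, 1), np.zeros((2, 2, 2)))
        return [DoseGrid(g.like(a)) for a in arrays]

    def _structures(self, ctv):
        empty = np.zeros((2, 2, 2), dtype=bool)
        return StructureSet({"prostate": ctv, "sv": empty,
                             "rectum": empty, "bladder": empty,
                             "bone": empty, "body": np.ones_like(ctv)})

    def test_single_scenario_identity(self):
        d = np.random.default_rng(0).uniform(size=(2, 2, 2))
        ctv = np.zeros((2, 2, 2), dtype=bool)
        ctv[0, 0, 0] = True
        wt, wo = worst_case_dose(self._doses([d]), self._structures(ctv))
        np.testing.assert_array_equal(wt.values, d)
        np.testing.assert_array_equal(wo.values, d)

    def test_min_inside_ctv_max_elsewhere(self):
        d = np.ones((2, 2, 2))
        ctv = np.zeros((2, 2, 2), dtype=bool)
        ctv[0, :, :] = True
        wt, wo = worst_case_dose(self._doses([d, 2 * d]),
                                 self._structures(ctv))
        assert np.all(wt.values[ctv] == 1.0)
        assert np.all(wo.values[~ctv] == 2.0)

    def test_matches_brute_force_per_voxel(self):
        rng = np.random.default_rng(4)
        arrays = [rng.uniform(size=(2, 2, 2)) for _ in range(9)]
        ctv = rng.uniform(size=(2, 2, 2)) > 0.5
        wt, wo = worst_case_dose(self._doses(arrays), self._structures(ctv))
        stack = np.stack(arrays)
        for idx in np.ndindex(2, 2, 2):
            col = stack[(slice(None),) + idx]
            if ctv[idx]:
                assert wt.values[idx] == col.min()
            else:
                assert wo.values[idx] == col.max()

    def test_empty_scenario_list_raises(self):
        with pytest.raises(ValueError):
            worst_case_dose([], self._structures(np.ones((2, 2, 2), bool)))


@pytest.fixture(scope="module")
def water_box_plan(water_box):
    return optimize_spot_weights(water_box, PlanningGoals(), RobustSetting(),
                                 BeamModel())


class TestPlanQuality:
    def test_water_box_meets_planning_goals(self, water_box, water_box_plan):
        dose = compute_dose(water_box_plan, water_box)
        ctv = water_box.structures.ctv
        d99 = dvh_index_d(compute_dvh(dose, ctv), 99.0)
        assert d99 >= 63.0
        assert dose_max(dose, ctv) < 69.3

    def test_weights_non_negative(self, water_box_plan):
        assert np.all(water_box_plan.weight >= 0)

    def test_objective_history_non_increasing(self, water_box_plan):
        hist = water_box_plan.meta["optimization"]["objective_history"]
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_determinism(self, reference):
        plans = [optimize_spot_weights(reference, PlanningGoals(),
                                       RobustSetting(), COHORT_BEAM)
                 for _ in range(2)]
        np.testing.assert_array_equal(plans[0].weight, plans[1].weight)

    def test_pelvic_plan_meets_goals(self, reference):
        plan = optimize_spot_weights(reference, PlanningGoals(),
                                     RobustSetting(), COHORT_BEAM)
        dose = compute_dose(plan, reference)
        s = reference.structures
        assert dvh_index_d(compute_dvh(dose, s.ctv), 99.0) >= 63.0
        assert dose_max(dose, s.ctv) < 69.3
        from adaptrt import dvh_index_v
        assert dvh_index_v(compute_dvh(dose, s["rectum"]), 50.0) < 20.0
        assert dvh_index_v(compute_dvh(dose, s["bladder"]), 30.0) < 30.0

    def test_robustness_dividend(self, reference):
        """The robust plan's worst-scenario CTV D99 exceeds that of a
        nominal-only plan."""
        robust = optimize_spot_weights(reference, PlanningGoals(),
                                       RobustSetting(), COHORT_BEAM)
        nominal_only = optimize_spot_weights(
            reference, PlanningGoals(),
            RobustSetting(setup_mm=0.0, range_pct=0.0), COHORT_BEAM)
        s = reference.structures

        def worst_d99(plan):
            doses = [compute_dose(plan, reference, sc)
                     for sc in build_scenarios(RobustSetting())]
            wt, _ = worst_case_dose(doses, s)
            return dvh_index_d(compute_dvh(wt, s.ctv), 99.0)

        assert worst_d99(robust) > worst_d99(nominal_only)
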