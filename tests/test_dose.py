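"""Dose engine: WEPL tracing, Bragg curve, spot dose, scenarios, RBE."""
from __future__ import annotations

import numpy as np
import pytest

from adaptrt import (BeamModel, Scenario, SpotPlan, VoxelGrid, WeplSampler,
                     bragg_depth_dose, compute_dose, dose_at_points,
                     trace_wepl, wepl_grid)


@pytest.fixture(scope="module")
def water_slab():
    g = VoxelGrid.from_extent((0, 0, 0), (99, 39, 39), (1.0, 1.0, 1.0))
    g.values[:] = 1.0
    return g


class TestTraceWepl:
    def test_uniform_water(self, water_slab):
        w = trace_wepl(water_slab, (-0.5, 20, 20), (1, 0, 0), [50.0, 100.0])
        np.testing.assert_allclose(w, [50.0, 100.0], atol=1e-9)

    def test_scales_linearly_with_rsp(self, water_slab):
        slab = water_slab.like(water_slab.values * 1.2)
        w = trace_wepl(slab, (-0.5, 20, 20), (1, 0, 0), [100.0])
        assert w[0] == pytest.approx(120.0)

    def test_heterogeneous_matches_fine_step_integration(self, water_slab):
        rng = np.random.default_rng(1)
        het = water_slab.like(rng.uniform(0.5, 1.5, water_slab.shape))
        entry = np.array([-0.5, 20.3, 17.7])
        u = np.array([1.0, 0.0, 0.0])
        depths = np.linspace(5, 100, 9)
        got = trace_wepl(het, entry, u, depths)
        # brute-force 0.01 mm step integration oracle
        fine = np.arange(0.005, 100, 0.01)
        pts = entry + fine[:, None] * u
        idx = np.clip(np.round(het.world_to_continuous_index(pts)).astype(int),
                      0, np.array(het.shape) - 1)
        r = het.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        cum = np.concatenate([[0], np.cumsum(r * 0.01)])
        oracle = np.interp(depths, np.concatenate([[0], fine + 0.005]), cum)
        np.testing.assert_allclose(got, oracle, atol=0.1)

    def test_oblique_ray_monotone(self, water_slab):
        u = np.array([0.8, 0.6, 0.0])
        w = trace_wepl(water_slab, (-0.5, 5.0, 20.0), u,
                       np.linspace(0, 60, 20))
        assert np.all(np.diff(w) >= 0)

    def test_ray_missing_grid_returns_empty(self, water_slab):
        w = trace_wepl(water_slab, (-10.0, 500.0, 20.0), (1, 0, 0), [10.0])
        assert w.size == 0

    def test_wepl_grid_matches_trace_at_voxel_centers(self, water_slab):
        rng = np.random.default_rng(3)
        het = water_slab.like(rng.uniform(0.8, 1.2, water_slab.shape))
        wg = wepl_grid(het, 0)
        i, j, k = 40, 12, 25
        depth = het.axis_coords(0)[i] - (-0.5)
        tr = trace_wepl(het, (-0.5, float(het.axis_coords(1)[j]),
                              float(het.axis_coords(2)[k])), (1, 0, 0),
                        [depth])
        assert wg.values[i, j, k] == pytest.approx(tr[0], abs=1e-6)


class TestBraggCurve:
    def test_peak_at_range_and_distal_zero(self):
        bm = BeamModel()
        z = np.linspace(0, 180, 5000)
        d = bragg_depth_dose(150.0, z, bm)
        assert z[np.argmax(d)] == pytest.approx(150.0, abs=0.1)
        assert bragg_depth_dose(150.0, 150.0 + bm.distal_cutoff_mm, bm) == 0.0

    def test_entrance_to_peak_ratio_in_band(self):
        bm = BeamModel()
        for r in (80.0, 150.0, 250.0):
            ratio = bragg_depth_dose(r, 0.0, bm) / bragg_depth_dose(r, r, bm)
            assert 0.2 <= ratio <= 0.5

    def test_distal_falloff_80_20_width(self):
        bm = BeamModel()
        z = np.linspace(150, 165, 30001)
        d = bragg_depth_dose(150.0, z, bm)
        z80 = z[np.argmax(d <= 0.8)]
        z20 = z[np.argmax(d <= 0.2)]
        assert (z20 - z80) == pytest.approx(bm.distal_falloff_mm, abs=0.05)

    def test_integral_matches_quadrature_oracle(self):
        bm = BeamModel()
        z = np.linspace(0, 170, 200001)
        d = bragg_depth_dose(160.0, z, bm)
        trapz = np.trapezoid(d, z)
        z2 = np.linspace(0, 170, 20001)
        coarse = np.trapezoid(bragg_depth_dose(160.0, z2, bm), z2)
        assert coarse == pytest.approx(trapz, rel=1e-3)


class TestComputeDose:
    def test_single_spot_matches_per_voxel_oracle(self, water_slab):
        bm = BeamModel()
        plan = SpotPlan([0], [20.0], [20.0], [60.0], [1000.0], bm)
        dg = compute_dose(plan, water_slab)
        pts = water_slab.voxel_centers()
        wepl = WeplSampler(water_slab)(0, pts)
        b = bragg_depth_dose(60.0, wepl, bm)
        s = bm.sigma_at(wepl)
        oracle = 1.1 * 1000.0 * b * np.exp(
            -0.5 * ((pts[:, 1] - 20) ** 2 + (pts[:, 2] - 20) ** 2) / s ** 2) \
            / (2 * np.pi * s ** 2)
        inside = np.hypot(pts[:, 1] - 20, pts[:, 2] - 20) < 3.0 * s
        got = dg.values.ravel()[inside]
        np.testing.assert_allclose(got, oracle[inside],
                                   atol=1e-12 * oracle.max())

    def test_linearity_in_weights(self, water_slab):
        bm = BeamModel()
        plan1 = SpotPlan([0, 1], [18.0, 22.0], [20.0, 20.0], [60.0, 55.0],
                         [500.0, 300.0], bm)
        plan2 = plan1.with_weights([1000.0, 600.0])
        d1 = compute_dose(plan1, water_slab).values
        d2 = compute_dose(plan2, water_slab).values
        np.testing.assert_allclose(d2, 2.0 * d1, atol=1e-9 * d1.max())

    def test_rbe_factor_applied_once(self, water_slab):
        bm = BeamModel()
        plan = SpotPlan([0], [20.0], [20.0], [60.0], [1.0], bm)
        pts = np.array([[60.0, 20.0, 20.0]])
        wepl = WeplSampler(water_slab)
        rbe_dose = dose_at_points(plan, wepl, pts)[0]
        w = wepl(0, pts)
        physical = (bragg_depth_dose(60.0, w, bm)
                    * 1.0 / (2 * np.pi * bm.sigma_at(w) ** 2))[0]
        assert rbe_dose == pytest.approx(1.1 * physical, rel=1e-12)

    def test_empty_plan_gives_zero_dose(self, water_slab):
        plan = SpotPlan([], [], [], [], [], BeamModel())
        dg = compute_dose(plan, water_slab)
        assert np.all(dg.values == 0)

    def test_opposed_field_mirror_symmetry(self):
        g = VoxelGrid.from_extent((-50, -20, -20), (50, 20, 20), (2., 2., 2.))
        g.values[:] = 1.0
        bm = BeamModel()
        plan = SpotPlan([0, 1], [0.0, 0.0], [0.0, 0.0], [60.0, 60.0],
                        [1.0, 1.0], bm)
        d = compute_dose(plan, g).values
        np.testing.assert_allclose(d, d[::-1, :, :], atol=1e-9 * d.max())

    def test_range_scale_moves_distal_edge_deeper(self, water_slab):
        bm = BeamModel()
        plan = SpotPlan([0], [20.0], [20.0], [60.0], [1.0], bm)

        def distal_80(scale):
            d = compute_dose(plan, water_slab,
                             Scenario(range_scale=scale)).values[:, 20, 20]
            x = water_slab.axis_coords(0)
            peak = d.max()
            deep = np.flatnonzero(d >= 0.8 * peak)
            return x[deep[-1]]

        # larger RSP scale = shorter range in patient; the error scenarios
        # bracket the nominal distal edge monotonically
        assert distal_80(0.965) > distal_80(1.0) > distal_80(1.035)

    def test_scenario_shift_translates_dose(self, water_slab):
        bm = BeamModel()
        plan = SpotPlan([0], [20.0], [20.0], [60.0], [1.0], bm)
        nominal = compute_dose(plan, water_slab).values
        shifted = compute_dose(plan, water_slab,
                               Scenario(shift_mm=(0, 3, 0))).values
        # dose(v) under a +3 mm shift equals nominal dose at v + 3 mm
        np.testing.assert_allclose(shifted[:, 10, :], nominal[:, 13, :],
                                   atol=1e-9 * nominal.max())
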