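"""Gamma analysis and statistical tests against closed-form oracles."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from adaptrt import (DoseGrid, VoxelGrid, gamma_analysis, mcnemar_test,
                     paired_t_test)


def _dose(arr, spacing=2.0):
    g = VoxelGrid((0, 0, 0), (spacing,) * 3, np.asarray(arr, float))
    return DoseGrid(g)


@pytest.fixture(scope="module")
def bumpy_dose():
    rng = np.random.default_rng(8)
    x, y, z = np.meshgrid(*[np.linspace(0, 1, 14)] * 3, indexing="ij")
    vals = 60.0 * np.exp(-((x - 0.5) ** 2 + (y - 0.5) ** 2 + (z - 0.5) ** 2)
                         / 0.12) + rng.uniform(0, 0.1, x.shape)
    return _dose(vals)


class TestGamma:
    def test_self_comparison_is_100_percent(self, bumpy_dose):
        for dd, dta in ((1.0, 1.0), (0.5, 0.5), (3.0, 3.0)):
            assert gamma_analysis(bumpy_dose, bumpy_dose, dd, dta) == 100.0

    def test_pass_rate_non_increasing_with_tighter_criteria(self, bumpy_dose):
        pert = _dose(bumpy_dose.values * 1.015)
        loose = gamma_analysis(bumpy_dose, pert, 3.0, 3.0)
        tight = gamma_analysis(bumpy_dose, pert, 1.0, 1.0)
        tighter = gamma_analysis(bumpy_dose, pert, 0.5, 0.5)
        assert loose >= tight >= tighter

    def test_shift_monotonicity(self, bumpy_dose):
        vals = bumpy_dose.values
        small = _dose(np.roll(vals, 1, axis=0))   # 2 mm shift
        large = _dose(np.roll(vals, 2, axis=0))   # 4 mm shift
        assert gamma_analysis(bumpy_dose, small, 1.0, 1.0) >= \
            gamma_analysis(bumpy_dose, large, 1.0, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        ref_vals = rng.uniform(10, 60, (5, 5, 5))
        ev_vals = ref_vals + rng.normal(0, 0.6, ref_vals.shape)
        ref, ev = _dose(ref_vals), _dose(ev_vals)
        dd, dta, step = 1.0, 2.5, 1.25
        got = gamma_analysis(ref, ev, dd, dta, 10.0, search_step_mm=step)

        # exhaustive oracle over the same candidate offsets
        from scipy.interpolate import RegularGridInterpolator
        axes = tuple(ref.grid.axis_coords(a) for a in range(3))
        interp = RegularGridInterpolator(axes, ev_vals, bounds_error=False,
                                         fill_value=None, method="linear")
        dmax = ref_vals.max()
        sel = ref_vals >= 0.1 * dmax
        pts = ref.grid.mask_centers(sel)
        dref = ref_vals[sel]
        offs = np.arange(-dta, dta + step / 2, step)
        n_pass = 0
        for p, dr in zip(pts, dref):
            best = np.inf
            for ox in offs:
                for oy in offs:
                    for oz in offs:
                        r2 = ox * ox + oy * oy + oz * oz
                        if r2 > dta * dta + 1e-12:
                            continue
                        q = np.clip(p + [ox, oy, oz],
                                    [a[0] for a in axes],
                                    [a[-1] for a in axes])
                        de = float(interp(q)[0])
                        g2 = r2 / dta ** 2 + ((de - dr) / (dd / 100 * dmax)) ** 2
                        best = min(best, g2)
            n_pass += best <= 1.0 + 1e-12
        oracle = 100.0 * n_pass / len(pts)
        assert got == pytest.approx(oracle, abs=1e-9)


class TestPairedT:
    def test_identical_samples(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.warns(UserWarning):
            r = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.p_value == 0.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(12)
        a = rng.normal(10, 2, 10)
        b = rng.normal(9, 2, 10)
        r = paired_t_test(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * sps.t.sf(abs(t_hand), len(d) - 1)
        assert r.statistic == pytest.approx(t_hand, abs=1e-10)
        assert r.p_value == pytest.approx(p_hand, abs=1e-10)


class TestMcNemar:
    def test_identical_flags(self):
        r = mcnemar_test([True, False, True], [True, False, True])
        assert r.p_value == 1.0

    def test_exact_binomial_oracle(self):
        # b = 10 discordant one way, c = 0: p = 2 * 0.5^10
        a = [True] * 10 + [True] * 5
        b = [False] * 10 + [True] * 5
        r = mcnemar_test(a, b)
        assert r.p_value == pytest.approx(2 * 0.5 ** 10, rel=1e-9)

    def test_chi_square_formula(self):
        # b = 30, c = 10 -> chi2 = (30-10)^2 / 40 = 10
        a = [True] * 30 + [False] * 10 + [True] * 5
        b = [False] * 30 + [True] * 10 + [True] * 5
        r = mcnemar_test(a, b)
        assert r.statistic == pytest.approx(10.0)
        assert r.p_value == pytest.approx(sps.chi2.sf(10.0, 1), rel=1e-9)

    def test_exact_asymptotic_switch_at_25_discordant(self):
        a24 = [True] * 24 + [True] * 3
        b24 = [False] * 24 + [True] * 3
        assert mcnemar_test(a24, b24).note == "exact binomial"
        a25 = [True] * 25 + [True] * 3
        b25 = [False] * 25 + [True] * 3
        assert mcnemar_test(a25, b25).note == "chi-square"
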