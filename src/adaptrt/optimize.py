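"""Worst-case robust spot-weight optimization (multi-field optimization).

The plan objective is evaluated on worst-case composite doses over the
robustness scenarios (voxel-wise minimum over scenarios inside the CTV for
under-dose, voxel-wise maximum for over-dose and organ-at-risk terms):

* CTV under-dose: one-sided quadratic below the prescription;
* CTV over-dose: one-sided quadratic above 110% of the prescription;
* rectum V50 < 20%, rectum V30 < 50%, bladder V30 < 30% as iteratively
  re-linearized DVH-point penalties (one-sided quadratic on the voxels that
  currently violate the volume constraint);
* a normal-tissue shell around the CTV capped at the Dmax goal.

Target penalties dominate the OAR penalties (target priority).  Minimization
is projected quasi-Newton (L-BFGS-B with non-negativity bounds) inside an
outer loop that refreshes the DVH-penalty voxel subsets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.optimize import minimize

from .beam import BeamModel, SpotPlan, place_spots
from .dose import DoseGrid, Scenario, WeplSampler, influence_matrix
from .grids import VoxelGrid


class PlanningError(RuntimeError):
    """Plan cannot be produced (empty CTV, target out of reach, ...)."""


@dataclass
class PlanningGoals:
    """Planning dose objectives/constraints (full-course Gy(RBE))."""

    prescription_gy: float = 63.0
    n_fractions: int = 21
    #: CTV D99 objective as a fraction of prescription
    d99_fraction: float = 1.0
    #: CTV Dmax objective as a fraction of prescription
    dmax_fraction: float = 1.10
    #: (structure, threshold Gy, max relative volume %)
    oar_constraints: tuple = (("rectum", 50.0, 20.0),
                              ("rectum", 30.0, 50.0),
                              ("bladder", 30.0, 30.0))
    weight_underdose: float = 300.0
    weight_overdose: float = 80.0
    weight_oar: float = 2.0
    #: small always-on pressure above each OAR threshold ("as low as
    #: possible" in addition to the hard volume constraint)
    weight_oar_soft: float = 0.15
    weight_shell: float = 1.0
    #: renormalize the final plan so nominal CTV D99 hits this fraction of
    #: prescription (clinical-style prescription normalization)
    normalize_d99_fraction: float = 1.005

    @property
    def d99_goal_gy(self) -> float:
        return self.d99_fraction * self.prescription_gy

    @property
    def dmax_goal_gy(self) -> float:
        return self.dmax_fraction * self.prescription_gy

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["oar_constraints"] = [list(c) for c in self.oar_constraints]
        return d

    @staticmethod
    def from_dict(d: dict) -> "PlanningGoals":
        d = dict(d)
        d["oar_constraints"] = tuple(tuple(c) for c in d["oar_constraints"])
        return PlanningGoals(**d)


@dataclass
class RobustSetting:
    """Worst-case robustness condition: set-up and range uncertainty."""

    setup_mm: float = 3.0
    range_pct: float = 3.5

    def __post_init__(self):
        if self.setup_mm < 0 or self.range_pct < 0:
            raise ValueError("uncertainty magnitudes must be >= 0")

    def to_dict(self) -> dict:
        return {"setup_mm": self.setup_mm, "range_pct": self.range_pct}


def build_scenarios(setting: RobustSetting) -> list[Scenario]:
    """Nominal + 6 axis-aligned isocenter shifts + 2 range scales.

    Shifts and range errors are evaluated separately (9 scenarios), not
    cross-producted.
    """
    scenarios = [Scenario.nominal()]
    if setting.setup_mm > 0:
        for axis in range(3):
            for sign in (+1.0, -1.0):
                shift = np.zeros(3)
                shift[axis] = sign * setting.setup_mm
                scenarios.append(Scenario(shift))
    if setting.range_pct > 0:
        for sign in (+1.0, -1.0):
            scenarios.append(Scenario(range_scale=1.0 + sign * setting.range_pct / 100.0))
    return scenarios


def worst_case_dose(per_scenario_doses: list[DoseGrid], structures
                    ) -> tuple[DoseGrid, DoseGrid]:
    """Voxel-wise worst case over scenarios: minimum inside the CTV
    (under-dose worst case), maximum elsewhere (over-dose worst case)."""
    if not per_scenario_doses:
        raise ValueError("empty scenario dose list")
    g0 = per_scenario_doses[0].grid
    for d in per_scenario_doses[1:]:
        if not d.grid.same_geometry(g0):
            raise ValueError("scenario doses not co-registered")
    stack = np.stack([d.values for d in per_scenario_doses])
    dmin = stack.min(axis=0)
    dmax = stack.max(axis=0)
    ctv = structures["ctv"]
    fc = per_scenario_doses[0].fraction_count_represented
    worst_target = np.where(ctv, dmin, stack[0])
    worst_oar = np.where(ctv, stack[0], dmax)
    return (DoseGrid(g0.like(worst_target), fraction_count_represented=fc),
            DoseGrid(g0.like(worst_oar), fraction_count_represented=fc))


# ---------------------------------------------------------------------------
# spot-weight optimization


def _sample_mask(mask: np.ndarray, max_n: int, rng: np.random.Generator):
    idx = np.argwhere(mask)
    if len(idx) <= max_n:
        return idx
    sel = rng.choice(len(idx), size=max_n, replace=False)
    return idx[np.sort(sel)]


@dataclass
class _EvalSets:
    pts: np.ndarray          # (N, 3) world points
    ctv: slice
    shell: slice
    oar: dict                # structure -> slice


def _build_eval_sets(anatomy, max_oar: int = 400, max_shell: int = 400,
                     max_ctv: int = 2500) -> _EvalSets:
    grid = anatomy.grid
    rng = np.random.default_rng(12345)   # fixed: plans must be deterministic
    ctv_mask = anatomy.structures.ctv
    if not np.any(ctv_mask):
        raise PlanningError("CTV is empty")
    shell_mask = binary_dilation(ctv_mask, iterations=max(
        1, int(round(8.0 / grid.spacing[0])))) & ~ctv_mask \
        & anatomy.structures["body"]
    blocks, slices, start = [], {}, 0

    def add(name, idx):
        nonlocal start
        blocks.append(grid.origin + idx * grid.spacing)
        slices[name] = slice(start, start + len(idx))
        start += len(idx)

    add("ctv", _sample_mask(ctv_mask, max_ctv, rng))
    add("shell", _sample_mask(shell_mask, max_shell, rng))
    for organ in ("rectum", "bladder"):
        add(organ, _sample_mask(anatomy.structures[organ], max_oar, rng))
    pts = np.concatenate(blocks, axis=0)
    return _EvalSets(pts, slices["ctv"], slices["shell"],
                     {o: slices[o] for o in ("rectum", "bladder")})


def optimize_spot_weights(anatomy, goals: PlanningGoals,
                          setting: RobustSetting,
                          beam: BeamModel | None = None,
                          spots: SpotPlan | None = None,
                          lateral_expand_mm: float = 0.0,
                          init_weights: np.ndarray | None = None,
                          max_outer: int = 6, max_inner: int = 40,
                          ftol_rel: float = 1e-5) -> SpotPlan:
    """Optimize non-negative spot weights against the worst-case composite
    dose over the robustness scenarios.  Deterministic for a fixed anatomy
    and initialization; returns the plan with convergence metadata.
    """
    beam = beam or BeamModel()
    wepl = WeplSampler(anatomy.rsp)
    ev = _build_eval_sets(anatomy)
    if spots is None:
        ctv_pts = anatomy.grid.mask_centers(anatomy.structures.ctv)
        spots = place_spots(wepl, ctv_pts, beam, goals.prescription_gy,
                            goals.n_fractions, lateral_expand_mm)
    if spots.n_spots == 0:
        raise PlanningError("no spots cover the CTV")

    scenarios = build_scenarios(setting)
    mats = [influence_matrix(spots, wepl, ev.pts, sc) for sc in scenarios]
    a_nom64 = mats[0].astype(np.float64)

    n_ctv = max(ev.ctv.stop - ev.ctv.start, 1)
    presc = goals.prescription_gy
    # penalize above the post-normalization Dmax budget so the final
    # prescription-normalized plan still respects the printed goal
    dmax_goal = goals.dmax_goal_gy / goals.normalize_d99_fraction

    # deterministic scale-correct start: nominal mean CTV dose = prescription
    if init_weights is not None:
        w0 = np.asarray(init_weights, float).copy()
    else:
        w0 = np.ones(spots.n_spots)
    mean0 = float(np.mean(a_nom64[ev.ctv] @ w0))
    if mean0 <= 0:
        raise PlanningError("CTV receives no dose from the spot lattice")
    w0 *= presc / mean0

    oar_sets: dict = {}

    def refresh_oar_sets(w):
        """Voxels currently violating each DVH constraint (worst-case max)."""
        w32 = w.astype(np.float32)
        doses = [m @ w32 for m in mats]
        dmax = np.max(doses, axis=0)
        oar_sets.clear()
        for organ, thr, vol_pct in goals.oar_constraints:
            sl = ev.oar[organ]
            d = dmax[sl]
            n = len(d)
            if n == 0:
                continue
            allowed = int(np.floor(vol_pct / 100.0 * n))
            order = np.argsort(d)[::-1]
            # voxels above the threshold but not in the allowed top fraction
            viol = order[allowed:]
            viol = viol[d[viol] > thr]
            oar_sets.setdefault((organ, thr, vol_pct), []).append(
                (sl, viol, n))

    def objective(w):
        w32 = w.astype(np.float32)
        stack = np.stack([m @ w32 for m in mats]).astype(np.float64)
        dmin = stack.min(axis=0)
        dmax = stack.max(axis=0)
        amin = stack.argmin(axis=0)
        amax = stack.argmax(axis=0)

        grad_min = np.zeros_like(dmin)
        grad_max = np.zeros_like(dmax)
        f = 0.0
        # CTV under-dose on worst-case min
        r = np.maximum(presc - dmin[ev.ctv], 0.0)
        f += goals.weight_underdose * np.sum(r * r) / n_ctv
        grad_min[ev.ctv] += goals.weight_underdose * (-2.0 * r) / n_ctv
        # CTV over-dose on worst-case max
        r = np.maximum(dmax[ev.ctv] - dmax_goal, 0.0)
        f += goals.weight_overdose * np.sum(r * r) / n_ctv
        grad_max[ev.ctv] += goals.weight_overdose * (2.0 * r) / n_ctv
        # shell hot-spot cap
        sl = ev.shell
        n_shell = max(sl.stop - sl.start, 1)
        r = np.maximum(dmax[sl] - dmax_goal, 0.0)
        f += goals.weight_shell * np.sum(r * r) / n_shell
        grad_max[sl] += goals.weight_shell * (2.0 * r) / n_shell
        # DVH-point OAR penalties on the frozen violating subsets
        for (organ, thr, vol_pct), entries in oar_sets.items():
            for sl2, viol, n in entries:
                if len(viol) == 0:
                    continue
                d = dmax[sl2][viol]
                r = np.maximum(d - thr, 0.0)
                f += goals.weight_oar * np.sum(r * r) / n
                idx = np.arange(sl2.start, sl2.stop)[viol]
                grad_max[idx] += goals.weight_oar * (2.0 * r) / n
        # soft "as low as possible" pressure over all OAR voxels above the
        # constraint threshold, active regardless of the volume budget
        if goals.weight_oar_soft > 0:
            for organ, thr, _ in goals.oar_constraints:
                sl2 = ev.oar[organ]
                n = max(sl2.stop - sl2.start, 1)
                r = np.maximum(dmax[sl2] - thr, 0.0)
                f += goals.weight_oar_soft * np.sum(r * r) / n
                grad_max[sl2] += goals.weight_oar_soft * (2.0 * r) / n

        grad = np.zeros_like(w)
        for s, m in enumerate(mats):
            gm = np.where(amin == s, grad_min, 0.0) + \
                 np.where(amax == s, grad_max, 0.0)
            grad += m.T @ gm.astype(np.float32)
        return f, grad

    w = w0
    history = []
    prev_f = None
    for outer in range(max_outer):
        refresh_oar_sets(w)
        res = minimize(objective, w, jac=True, method="L-BFGS-B",
                       bounds=[(0.0, None)] * len(w),
                       options={"maxiter": max_inner, "ftol": 1e-12,
                                "gtol": 1e-12})
        w = res.x
        history.append(float(res.fun))
        if prev_f is not None and \
                prev_f - res.fun <= ftol_rel * max(abs(prev_f), 1e-12):
            break
        prev_f = float(res.fun)

    # prescription normalization on nominal CTV D99 (voxel percentile)
    d_ctv = a_nom64[ev.ctv] @ w
    d99 = float(np.percentile(d_ctv, 1.0))
    target = goals.normalize_d99_fraction * presc
    if d99 <= 0:
        raise PlanningError("optimization produced zero CTV dose")
    w = w * (target / d99)

    final_doses = [m.astype(np.float64) @ w for m in mats]
    stack = np.stack(final_doses)
    report = {
        "objective_history": history,
        "outer_iterations": len(history),
        "n_scenarios": len(scenarios),
        "scenarios": [{"shift_mm": s.shift_mm.tolist(),
                       "range_scale": s.range_scale} for s in scenarios],
        "nominal_ctv_d99": float(np.percentile(stack[0][ev.ctv], 1.0)),
        "worst_ctv_d99": float(np.percentile(stack.min(axis=0)[ev.ctv], 1.0)),
        "nominal_ctv_dmax": float(stack[0][ev.ctv].max()),
        "normalization_factor": float(target / d99),
    }
    for organ, thr, vol_pct in goals.oar_constraints:
        sl = ev.oar[organ]
        if sl.stop > sl.start:
            v = 100.0 * float(np.mean(stack[0][sl] >= thr))
            report[f"nominal_{organ}_v{int(thr)}"] = v
    return spots.with_weights(w, optimization=report)
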