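"""In-silico trial orchestration: NART vs DART over a synthetic cohort.

For every patient, a robust original plan is optimized on the planning
phantom.  Each treatment day a new anatomy is drawn, aligned the clinical
way (bone matching, then prostate center to isocenter), and dosed:

* NART delivers the original plan to every daily anatomy;
* DART re-optimizes the plan on each daily anatomy with the same goals and
  the same 3 mm / 3.5% robust setting.

Fraction doses are evaluated against the daily structures after x21 scaling
(the worst-case single-day extrapolation) and accumulated on the planning
anatomy through the generator's exact deformation for the accumulated-dose
comparison.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .accumulate import AccumulatedDose, accumulate, map_dose_to_reference
from .align import align_daily
from .beam import BeamModel, SpotPlan
from .dose import DoseGrid, Scenario, WeplSampler, compute_dose
from .dvh import compute_dvh, dvh_index_d, dvh_index_v
from .goals import (GoalReport, achievement_rates, compute_goal_report,
                    reports_to_frame)
from .grids import VoxelGrid
from .optimize import (PlanningGoals, RobustSetting, build_scenarios,
                       optimize_spot_weights)
from .phantom import (AnatomyInstance, PhantomConfig, StructureSet,
                      build_reference_phantom, sample_patient_config)
from .stats import mcnemar_test, paired_t_test
from .variation import VariationParams, sample_daily_anatomy

log = logging.getLogger(__name__)

#: beam parameterization used for cohort runs (desk-scale problem size)
COHORT_BEAM = BeamModel(sigma0_mm=6.0, layer_spacing_mm=6.0)


class StrategyError(RuntimeError):
    pass


@dataclass
class TrialConfig:
    """Shape and seeds of the simulated trial (defaults: 23 patients x 21
    fractions = 483 daily anatomies)."""

    n_patients: int = 23
    n_fractions: int = 21
    master_seed: int = 42
    grid_spacing_mm: float = 5.0
    goals: PlanningGoals = field(default_factory=PlanningGoals)
    robust: RobustSetting = field(default_factory=RobustSetting)
    variation: VariationParams = field(default_factory=VariationParams)
    beam: BeamModel = field(default_factory=lambda: replace(COHORT_BEAM))
    base_phantom: PhantomConfig | None = None
    #: widen the per-patient spot lattice to pre-cover daily variation
    lateral_expand_mm: float = 4.0
    dose_box_margin_mm: float = 16.0
    strategies: tuple = ("nart", "dart")
    #: iteration caps for the warm-started daily re-optimization
    dart_max_outer: int = 3
    dart_max_inner: int = 20

    def patient_seed(self, patient: int) -> int:
        return (int(self.master_seed) * 100003 + patient) % (2 ** 31)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients, "n_fractions": self.n_fractions,
            "master_seed": self.master_seed,
            "grid_spacing_mm": self.grid_spacing_mm,
            "goals": self.goals.to_dict(), "robust": self.robust.to_dict(),
            "variation": self.variation.to_dict(),
            "beam": self.beam.to_dict(),
            "lateral_expand_mm": self.lateral_expand_mm,
            "dose_box_margin_mm": self.dose_box_margin_mm,
            "strategies": list(self.strategies),
        }

    @staticmethod
    def from_dict(d: dict) -> "TrialConfig":
        d = dict(d)
        d["goals"] = PlanningGoals.from_dict(d["goals"])
        d["robust"] = RobustSetting(**d["robust"])
        d["variation"] = VariationParams.from_dict(d["variation"])
        d["beam"] = BeamModel.from_dict(d["beam"])
        d["strategies"] = tuple(d["strategies"])
        return TrialConfig(**d)


# ---------------------------------------------------------------------------
# helpers


def _structure_box(anatomy: AnatomyInstance, margin_mm: float):
    """Index-aligned sub-grid slices covering CTV + OARs with margin."""
    union = (anatomy.structures.ctv | anatomy.structures["rectum"]
             | anatomy.structures["bladder"])
    idx = np.argwhere(union)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    m = np.ceil(margin_mm / anatomy.grid.spacing).astype(int)
    lo = np.maximum(lo - m, 0)
    hi = np.minimum(hi + m, np.array(anatomy.grid.shape) - 1)
    return tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))


def _sub_grid(grid: VoxelGrid, slices) -> VoxelGrid:
    origin = grid.origin + np.array([s.start for s in slices]) * grid.spacing
    return VoxelGrid(origin, grid.spacing, grid.values[slices])


def _sub_structures(structures: StructureSet, slices) -> StructureSet:
    return StructureSet({k: v[slices] for k, v in structures.masks.items()})


def scale_fraction_dose(fraction_dose: DoseGrid, n_fractions: int = 21) -> DoseGrid:
    """x21 scaling of a single-fraction dose: the worst-case extrapolation of
    one day's anatomy to the whole course."""
    if fraction_dose.fraction_count_represented != 1:
        raise ValueError("input already represents more than one fraction")
    return fraction_dose.scaled(float(n_fractions), fraction_count=n_fractions)


def patient_reference(config: TrialConfig, patient: int) -> AnatomyInstance:
    """Planning phantom of one cohort patient (deterministic in the master
    seed)."""
    rng = np.random.default_rng([config.master_seed, patient])
    base = config.base_phantom or PhantomConfig()
    cfg = replace(sample_patient_config(rng, base),
                  spacing=(config.grid_spacing_mm,) * 3)
    return build_reference_phantom(cfg)


def optimize_original_plan(config: TrialConfig,
                           reference: AnatomyInstance) -> SpotPlan:
    return optimize_spot_weights(
        reference, config.goals, config.robust, config.beam,
        lateral_expand_mm=config.lateral_expand_mm)


# ---------------------------------------------------------------------------
# strategy simulation


@dataclass
class FractionOutcome:
    patient: int
    fraction: int
    strategy: str
    report: GoalReport | None
    mapped_dose: DoseGrid | None
    failed: bool = False
    error: str = ""


@dataclass
class StrategyResult:
    """Per-patient result of one strategy over all fractions."""

    patient: int
    strategy: str
    fractions: list
    accumulated: AccumulatedDose | None
    accumulated_report: GoalReport | None
    timing_s: float = 0.0

    @property
    def fraction_reports(self) -> list:
        return [f.report for f in self.fractions if f.report is not None]


def _run_strategy(strategy: str, config: TrialConfig, patient: int,
                  reference: AnatomyInstance, original_plan: SpotPlan,
                  daily_instances: list,
                  aligned_instances: list | None = None) -> StrategyResult:
    t_start = time.time()
    slices = _structure_box(reference, config.dose_box_margin_mm)
    n_fx = config.n_fractions
    outcomes = []
    for f, daily in enumerate(daily_instances):
        try:
            if aligned_instances is not None and aligned_instances[f] is not None:
                aligned = aligned_instances[f]
            else:
                aligned, _ = align_daily(daily, reference)
            if strategy == "dart":
                plan = optimize_spot_weights(
                    aligned, config.goals, config.robust, config.beam,
                    spots=original_plan, init_weights=original_plan.weight,
                    max_outer=config.dart_max_outer,
                    max_inner=config.dart_max_inner)
            else:
                plan = original_plan
            box = _sub_grid(aligned.grid, slices)
            frac = compute_dose(plan, aligned, Scenario.nominal(),
                                eval_grid=box).scaled(1.0 / n_fx,
                                                      fraction_count=1)
            scaled = scale_fraction_dose(frac, n_fx)
            report = compute_goal_report(
                scaled, _sub_structures(aligned.structures, slices),
                config.goals.prescription_gy,
                patient=patient, fraction=f, strategy=strategy, kind="fractional")
            ref_box = _sub_grid(reference.grid, slices)
            box_pts = ref_box.voxel_centers()
            daily_pts = aligned.deformation.to_daily(box_pts)
            vals = np.maximum(frac.grid.sample(daily_pts, order=1, cval=0.0),
                              0.0).reshape(ref_box.shape)
            mapped = DoseGrid(ref_box.like(vals), fraction_count_represented=1)
            outcomes.append(FractionOutcome(patient, f, strategy, report, mapped))
        except Exception as exc:  # noqa: BLE001 - fraction flagged, not lost
            log.warning("patient %d fraction %d (%s) failed: %s",
                        patient, f, strategy, exc)
            outcomes.append(FractionOutcome(patient, f, strategy, None, None,
                                            failed=True, error=str(exc)))
    mapped = [o.mapped_dose for o in outcomes if o.mapped_dose is not None]
    acc = acc_report = None
    if len(mapped) == n_fx:
        acc = accumulate(mapped, expected_count=n_fx,
                         provenance=[{"patient": patient,
                                      "seed": config.patient_seed(patient)}])
        acc_report = compute_goal_report(
            acc.dose, _sub_structures(reference.structures, slices),
            config.goals.prescription_gy,
            patient=patient, strategy=strategy, kind="accumulated")
    return StrategyResult(patient, strategy, outcomes, acc, acc_report,
                          timing_s=time.time() - t_start)


def run_nart(config: TrialConfig, patient: int, reference: AnatomyInstance,
             original_plan: SpotPlan, daily_instances: list,
             aligned_instances: list | None = None) -> StrategyResult:
    """Non-adaptive strategy: the original plan delivered every day."""
    return _run_strategy("nart", config, patient, reference, original_plan,
                         daily_instances, aligned_instances)


def run_dart(config: TrialConfig, patient: int, reference: AnatomyInstance,
             original_plan: SpotPlan, daily_instances: list,
             aligned_instances: list | None = None) -> StrategyResult:
    """Daily-adaptive strategy: spot weights re-optimized on each daily
    anatomy (same goals, same robust setting, same spot lattice)."""
    return _run_strategy("dart", config, patient, reference, original_plan,
                         daily_instances, aligned_instances)


def evaluate_plan_robustness(plan: SpotPlan, anatomy: AnatomyInstance,
                             setting: RobustSetting | None = None,
                             include_nominal_control: bool = True
                             ) -> pd.DataFrame:
    """Error-scenario evaluation of a plan: 6 isocenter shifts and +-range%
    HU scalings, reported as deltas of CTV D99, rectum V60 and bladder V60
    versus the unperturbed plan."""
    setting = setting or RobustSetting()
    slices = _structure_box(anatomy, 16.0)
    box = _sub_grid(anatomy.grid, slices)
    structs = _sub_structures(anatomy.structures, slices)

    def indices_for(dose: DoseGrid) -> dict:
        out = {"ctv_d99": dvh_index_d(compute_dvh(dose, structs["ctv"]), 99.0)}
        for organ in ("rectum", "bladder"):
            out[f"{organ}_v60"] = dvh_index_v(
                compute_dvh(dose, structs[organ]), 60.0)
        return out

    base = indices_for(compute_dose(plan, anatomy, eval_grid=box))
    rows = []
    scenarios = [("nominal", Scenario.nominal())] if include_nominal_control else []
    for sc in build_scenarios(setting)[1:]:
        if sc.range_scale != 1.0:
            name = f"hu{'+' if sc.range_scale > 1 else '-'}{setting.range_pct}%"
        else:
            ax = int(np.flatnonzero(sc.shift_mm)[0])
            sgn = "+" if sc.shift_mm[ax] > 0 else "-"
            name = f"shift{'xyz'[ax]}{sgn}{setting.setup_mm:g}mm"
        scenarios.append((name, sc))
    for name, sc in scenarios:
        if sc.range_scale != 1.0:
            # HU perturbation applied voxel-by-voxel, then RSP recomputed
            pert = AnatomyInstance(
                grid=anatomy.grid.like(anatomy.grid.values * sc.range_scale),
                structures=anatomy.structures, geometry=anatomy.geometry,
                config=anatomy.config, isocenter_mm=anatomy.isocenter)
            dose = compute_dose(plan, pert, Scenario.nominal(), eval_grid=box)
        else:
            dose = compute_dose(plan, anatomy, sc, eval_grid=box)
        vals = indices_for(dose)
        rows.append({"scenario": name,
                     **{f"d_{k}": vals[k] - base[k] for k in base}})
    df = pd.DataFrame(rows).set_index("scenario")
    df.attrs["baseline"] = base
    return df


# ---------------------------------------------------------------------------
# whole-trial driver and results container


@dataclass
class TrialResults:
    """Cohort-level results with summary statistics.

    ``fractional`` and ``accumulated`` are long-format tables (one row per
    report-index); per-patient strategy results are kept in ``patients``.
    """

    config: TrialConfig
    patients: dict
    fractional: pd.DataFrame
    accumulated: pd.DataFrame

    def _reports(self, strategy: str, kind: str) -> list:
        out = []
        for (p, s), res in self.patients.items():
            if s != strategy:
                continue
            if kind == "fractional":
                out.extend(res.fraction_reports)
            elif res.accumulated_report is not None:
                out.append(res.accumulated_report)
        return out

    def achievement(self, strategy: str, kind: str = "fractional") -> pd.Series:
        return achievement_rates(self._reports(strategy, kind), "clinical")

    def index_values(self, strategy: str, index: str,
                     kind: str = "accumulated") -> np.ndarray:
        df = self.accumulated if kind == "accumulated" else self.fractional
        sel = df[(df["strategy"] == strategy) & (df["index"] == index)]
        return sel.sort_values(["patient"] + (
            ["fraction"] if kind == "fractional" else []))["value"].to_numpy()

    def compare(self, index: str, kind: str = "accumulated") -> dict:
        """NART vs DART paired comparison of one DVH index."""
        a = self.index_values("nart", index, kind)
        b = self.index_values("dart", index, kind)
        t = paired_t_test(a, b)
        return {"index": index, "kind": kind,
                "nart_mean": float(a.mean()), "nart_sd": float(a.std(ddof=1)),
                "dart_mean": float(b.mean()), "dart_sd": float(b.std(ddof=1)),
                "t": t.statistic, "p": t.p_value}

    def goal_comparison(self, index: str, kind: str = "fractional") -> dict:
        """NART vs DART clinical-goal achievement with McNemar's test."""
        fa = self._flags("nart", index, kind)
        fb = self._flags("dart", index, kind)
        m = mcnemar_test(fa, fb)
        return {"index": index, "kind": kind,
                "nart_rate": 100.0 * float(np.mean(fa)),
                "dart_rate": 100.0 * float(np.mean(fb)),
                "statistic": m.statistic, "p": m.p_value, "note": m.note}

    def _flags(self, strategy: str, index: str, kind: str) -> np.ndarray:
        reps = self._reports(strategy, kind)
        return np.array([r.clinical_pass[index] for r in reps], dtype=bool)

    def summary(self) -> str:
        lines = ["In-silico NART vs DART trial "
                 f"({self.config.n_patients} patients x "
                 f"{self.config.n_fractions} fractions, "
                 f"seed {self.config.master_seed})", ""]
        both = set(self.config.strategies) >= {"nart", "dart"}
        lines.append("Accumulated dose (per patient):")
        for index in ("ctv_d99", "prostate_d99", "sv_d99", "rectum_v50",
                      "bladder_v63_ml"):
            if both:
                c = self.compare(index)
                lines.append(
                    f"  {index:15s} NART {c['nart_mean']:6.2f} +/- {c['nart_sd']:5.2f}"
                    f"   DART {c['dart_mean']:6.2f} +/- {c['dart_sd']:5.2f}"
                    f"   p={c['p']:.4f}")
            else:
                s = self.config.strategies[0]
                v = self.index_values(s, index)
                lines.append(f"  {index:15s} {s.upper()} {v.mean():6.2f} "
                             f"+/- {v.std(ddof=1):5.2f}")
        lines.append("")
        lines.append("Clinical-goal achievement, fractional x21 doses (%):")
        for index in ("ctv_d99", "prostate_d99", "sv_d99", "rectum_dmax",
                      "rectum_v50", "bladder_v30", "bladder_v63_ml"):
            if both:
                g = self.goal_comparison(index)
                lines.append(f"  {index:15s} NART {g['nart_rate']:6.1f}"
                             f"   DART {g['dart_rate']:6.1f}   p={g['p']:.4f}")
            else:
                s = self.config.strategies[0]
                f = self._flags(s, index, "fractional")
                lines.append(f"  {index:15s} {s.upper()} {100*np.mean(f):6.1f}")
        return "\n".join(lines)


def run_patient(config: TrialConfig, patient: int) -> dict:
    """Simulate one patient under the configured strategies."""
    reference = patient_reference(config, patient)
    plan = optimize_original_plan(config, reference)
    params = config.variation.with_patient_offset(
        np.random.default_rng([config.master_seed, patient, 7]))
    seed = config.patient_seed(patient)
    daily = [sample_daily_anatomy(reference, params, f, seed)
             for f in range(config.n_fractions)]
    # clinical alignment is strategy-independent: do it once per fraction
    aligned = []
    for d in daily:
        try:
            aligned.append(align_daily(d, reference)[0])
        except Exception as exc:  # noqa: BLE001
            log.warning("patient %d alignment failed: %s", patient, exc)
            aligned.append(None)
    out = {}
    for strategy in config.strategies:
        runner = run_dart if strategy == "dart" else run_nart
        out[(patient, strategy)] = runner(config, patient, reference, plan,
                                          daily, aligned)
    return out


def run_trial(config: TrialConfig | None = None,
              progress: bool = False) -> TrialResults:
    """Run the full cohort trial; deterministic in ``config.master_seed``."""
    config = config or TrialConfig()
    patients: dict = {}
    for p in range(config.n_patients):
        t0 = time.time()
        patients.update(run_patient(config, p))
        if progress:
            print(f"patient {p + 1}/{config.n_patients} "
                  f"done in {time.time() - t0:.1f} s", flush=True)
    frac_reports, acc_reports = [], []
    for res in patients.values():
        frac_reports.extend(res.fraction_reports)
        if res.accumulated_report is not None:
            acc_reports.append(res.accumulated_report)
    return TrialResults(config, patients,
                        fractional=reports_to_frame(frac_reports),
                        accumulated=reports_to_frame(acc_reports))
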