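"""DVH indices and clinical/planning goal scoring.

Planning goals (on the original plan): CTV D99 > prescription, CTV Dmax <
110% of prescription, rectum V50 < 20%, rectum V30 < 50%, bladder V30 < 30%.

Clinical goals (per-fraction x21-scaled and accumulated doses): D99 of CTV,
prostate and SV above 95% of prescription (59.85 Gy(RBE) for 63 Gy(RBE)),
rectum Dmax < 66 Gy(RBE), the rectum/bladder relative-volume goals above,
and bladder V63 < 10 ml — the absolute-volume bladder index that is robust
to a truncated bladder field of view.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose import DoseGrid
from .dvh import compute_dvh, dose_max, dvh_index_d, dvh_index_v
from .phantom import StructureSet

#: evaluation indices: name -> (structure, kind, argument)
INDEX_DEFS = {
    "ctv_d99": ("ctv", "D", 99.0),
    "prostate_d99": ("prostate", "D", 99.0),
    "sv_d99": ("sv", "D", 99.0),
    "rectum_dmax": ("rectum", "Dmax", None),
    "rectum_v30": ("rectum", "V", 30.0),
    "rectum_v50": ("rectum", "V", 50.0),
    "rectum_v60": ("rectum", "V", 60.0),
    "bladder_v30": ("bladder", "V", 30.0),
    "bladder_v60": ("bladder", "V", 60.0),
    "bladder_v63_ml": ("bladder", "Vml", 63.0),
}


def planning_goals(prescription_gy: float = 63.0) -> dict:
    """Planning-goal thresholds: name -> (op, limit)."""
    return {
        "ctv_d99": (">", prescription_gy),
        "ctv_dmax": ("<", 1.10 * prescription_gy),
        "rectum_v30": ("<", 50.0),
        "rectum_v50": ("<", 20.0),
        "bladder_v30": ("<", 30.0),
    }


def clinical_goals(prescription_gy: float = 63.0) -> dict:
    """Clinical-goal thresholds; target D99 goals are 95% of prescription."""
    d99 = 0.95 * prescription_gy
    return {
        "ctv_d99": (">", d99),
        "prostate_d99": (">", d99),
        "sv_d99": (">", d99),
        "rectum_dmax": ("<", 66.0),
        "rectum_v30": ("<", 50.0),
        "rectum_v50": ("<", 20.0),
        "bladder_v30": ("<", 30.0),
        "bladder_v63_ml": ("<", 10.0),
    }


@dataclass
class GoalReport:
    """Per-structure DVH indices with pass/fail flags."""

    indices: dict
    planning_pass: dict
    clinical_pass: dict
    prescription_gy: float = 63.0
    meta: dict = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series(self.indices)


def _check(value: float, op: str, limit: float) -> bool:
    return value > limit if op == ">" else value < limit


def compute_goal_report(dose: DoseGrid, structures: StructureSet,
                        prescription_gy: float = 63.0,
                        bin_width: float = 0.05, **meta) -> GoalReport:
    """Evaluate all DVH indices of one dose distribution and score them
    against the planning and clinical goals."""
    dvhs = {}
    for s in ("ctv", "prostate", "sv", "rectum", "bladder"):
        dvhs[s] = compute_dvh(dose, structures[s], bin_width, structure=s)
    indices = {}
    for name, (s, kind, arg) in INDEX_DEFS.items():
        if kind == "D":
            indices[name] = dvh_index_d(dvhs[s], arg)
        elif kind == "V":
            indices[name] = dvh_index_v(dvhs[s], arg)
        elif kind == "Vml":
            indices[name] = dvh_index_v(dvhs[s], arg, absolute=True)
        else:
            indices[name] = dose_max(dose, structures[s])
    indices["ctv_dmax"] = dose_max(dose, structures["ctv"])

    p_pass = {k: _check(indices[k], *v)
              for k, v in planning_goals(prescription_gy).items()}
    c_pass = {k: _check(indices[k], *v)
              for k, v in clinical_goals(prescription_gy).items()}
    return GoalReport(indices, p_pass, c_pass, prescription_gy, meta)


def achievement_rates(reports: list[GoalReport],
                      which: str = "clinical") -> pd.Series:
    """Percent of reports passing each goal (regenerable from the stored
    per-report flags alone)."""
    if not reports:
        raise ValueError("no reports")
    key = "clinical_pass" if which == "clinical" else "planning_pass"
    frame = pd.DataFrame([getattr(r, key) for r in reports])
    return 100.0 * frame.mean()


def reports_to_frame(reports: list[GoalReport]) -> pd.DataFrame:
    """Long-format table (one row per report-index) with goal pass flags."""
    rows = []
    for r in reports:
        cg = clinical_goals(r.prescription_gy)
        for name, value in r.indices.items():
            rows.append({**r.meta, "index": name, "value": value,
                         "clinical_goal": cg.get(name, (None, np.nan))[1],
                         "clinical_pass": r.clinical_pass.get(name),
                         "planning_pass": r.planning_pass.get(name)})
    return pd.DataFrame(rows)
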