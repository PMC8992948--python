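"""Shared fixtures.

The expensive cohort simulation (23 patients x 21 fractions on the coarse
grid; daily-adaptive for every patient, non-adaptive for a paired subset)
is session-scoped and shared between the acceptance-level checks;
everything else uses small phantoms built on the fly.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from adaptrt import (PhantomConfig, TrialConfig, VariationParams,
                     build_reference_phantom, build_water_box_phantom,
                     run_trial)

COARSE_SPACING = (5.0, 5.0, 5.0)


@pytest.fixture(scope="session")
def coarse_config() -> PhantomConfig:
    return replace(PhantomConfig(), spacing=COARSE_SPACING)


@pytest.fixture(scope="session")
def reference(coarse_config):
    """Baseline pelvic phantom on the coarse simulation grid."""
    return build_reference_phantom(coarse_config)


@pytest.fixture(scope="session")
def water_box():
    return build_water_box_phantom()


@pytest.fixture(scope="session")
def volume_draws_483(reference):
    """Measured percent volume differences for 483 daily draws (23 x 21),
    on the fine measurement lattice."""
    from adaptrt import sample_daily_volume_changes
    params = VariationParams()
    res = {o: [] for o in ("prostate", "sv", "rectum", "bladder")}
    for p in range(23):
        for f in range(21):
            vc = sample_daily_volume_changes(reference, params, f,
                                             seed=1000 + p)
            for o, v in vc.items():
                res[o].append(v)
    return {o: np.asarray(v) for o, v in res.items()}


#: patients simulated under BOTH strategies (the strategy-ordering checks
#: need a paired subset; DART runs for the whole cohort)
N_PAIRED = 12


@pytest.fixture(scope="session")
def cohort_trial():
    """Full-shape cohort run (23 x 21) at the desk-scale problem size:
    DART for all patients, NART for the first N_PAIRED; backs the
    goal-attainment, accumulated-coverage and strategy-ordering checks."""
    from adaptrt.goals import reports_to_frame
    from adaptrt.trial import TrialResults, run_patient

    cfg = TrialConfig(master_seed=1)
    patients = {}
    for p in range(cfg.n_patients):
        pcfg = replace(cfg, strategies=("nart", "dart") if p < N_PAIRED
                       else ("dart",))
        patients.update(run_patient(pcfg, p))
    frac, acc = [], []
    for res in patients.values():
        frac.extend(res.fraction_reports)
        if res.accumulated_report is not None:
            acc.append(res.accumulated_report)
    return TrialResults(cfg, patients, fractional=reports_to_frame(frac),
                        accumulated=reports_to_frame(acc))
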