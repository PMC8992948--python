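"""3-D global gamma analysis.

gamma(x) = min over evaluated positions r of
    sqrt((|r - x| / dta)^2 + ((D_e(r) - D_r(x)) / (dd% x Dmax_ref))^2),
with the dose difference normalized to the reference maximum (global gamma)
and reference voxels below a low-dose cutoff excluded.  A voxel passes when
gamma <= 1; only candidate offsets with |r - x| <= dta can yield gamma <= 1,
so the search is restricted to a sphere of radius dta sampled at sub-voxel
steps with trilinear interpolation of the evaluated dose.
"""
from __future__ import annotations

import numpy as np

from .dose import DoseGrid


def gamma_analysis(reference: DoseGrid, evaluated: DoseGrid,
                   dd_percent: float = 1.0, dta_mm: float = 1.0,
                   dose_cutoff_percent: float = 10.0,
                   search_step_mm: float | None = None) -> float:
    """Global gamma pass rate in percent."""
    ref = reference.grid
    ev = evaluated.grid
    dmax = float(ref.values.max())
    if dmax <= 0:
        raise ValueError("reference dose is empty")
    dd_abs = dd_percent / 100.0 * dmax
    cutoff = dose_cutoff_percent / 100.0 * dmax
    sel = ref.values >= cutoff
    if not np.any(sel):
        raise ValueError("no reference voxels above the dose cutoff")
    pts = ref.mask_centers(sel)
    dref = ref.values[sel]

    step = search_step_mm if search_step_mm is not None else dta_mm / 2.0
    offs = np.arange(-dta_mm, dta_mm + step / 2, step)
    gamma_sq = np.full(len(pts), np.inf)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                r2 = ox * ox + oy * oy + oz * oz
                if r2 > dta_mm * dta_mm + 1e-12:
                    continue
                de = ev.sample(pts + np.array([ox, oy, oz]), order=1,
                               mode="nearest")
                g2 = r2 / (dta_mm * dta_mm) + ((de - dref) / dd_abs) ** 2
                np.minimum(gamma_sq, g2, out=gamma_sq)
    return 100.0 * float(np.mean(gamma_sq <= 1.0 + 1e-12))
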