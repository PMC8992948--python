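"""HU to relative proton stopping power (RSP) conversion.

The phantom assigns class-constant HU per tissue; the calibration below is a
piecewise-linear monotone stoichiometric-style curve anchored at air
(-1000 HU -> 0.001) and water (0 HU -> 1.0), with a single bone slope.  The
3.5% range uncertainty of robust planning is modelled as a multiplicative
perturbation of this curve's output (or equivalently of the HU input, since
the curve is piecewise linear per tissue class).
"""
from __future__ import annotations

import logging

import numpy as np

from .grids import VoxelGrid

log = logging.getLogger(__name__)

HU_MIN, HU_MAX = -1000.0, 3000.0

#: (HU, RSP) anchor points, strictly increasing in both columns.
DEFAULT_HU_RSP_TABLE: tuple[tuple[float, float], ...] = (
    (-1000.0, 0.001),
    (0.0, 1.0),
    (1000.0, 1.56),
    (3000.0, 2.50),
)


def hu_to_stopping_power(hu_grid: VoxelGrid,
                         table=DEFAULT_HU_RSP_TABLE) -> VoxelGrid:
    """Convert an HU volume to relative stopping power.

    HU outside [-1000, 3000] are clamped (with a log warning), matching how a
    TPS sanitises out-of-range voxels.
    """
    hu_pts = np.array([p[0] for p in table], dtype=float)
    rsp_pts = np.array([p[1] for p in table], dtype=float)
    if np.any(np.diff(hu_pts) <= 0) or np.any(np.diff(rsp_pts) <= 0):
        raise ValueError("calibration table must be strictly monotone")
    hu = np.asarray(hu_grid.values, dtype=float)
    n_out = int(np.sum((hu < HU_MIN) | (hu > HU_MAX)))
    if n_out:
        log.warning("clamping %d HU values outside [%g, %g]", n_out, HU_MIN, HU_MAX)
        hu = np.clip(hu, HU_MIN, HU_MAX)
    rsp = np.interp(hu, hu_pts, rsp_pts)
    return hu_grid.like(rsp)
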