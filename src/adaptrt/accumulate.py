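"""Deformable dose accumulation onto the planning anatomy.

Each fraction dose (computed on the couch-corrected daily anatomy) is pulled
back to planning coordinates through the generator's exact deformation and
the 21 mapped fraction doses are summed voxel-wise — the synthetic analogue
of DIR-based dose accumulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import DoseGrid
from .grids import VoxelGrid
from .phantom import AnatomyInstance


class AccumulationError(RuntimeError):
    pass


@dataclass
class AccumulatedDose:
    """Sum of per-fraction doses mapped onto the planning grid."""

    dose: DoseGrid
    fraction_doses_mapped: int
    provenance: list = field(default_factory=list)


def map_dose_to_reference(fraction_dose: DoseGrid, daily: AnatomyInstance,
                          reference: AnatomyInstance) -> DoseGrid:
    """Pull one fraction's dose back onto the planning grid.

    For every planning voxel x the mapped value is the trilinear sample of
    the fraction dose at the daily-coordinate image of x under the
    generator's deformation (zero outside the daily dose grid; the count of
    such voxels is recorded in the grid metadata via the return value's
    ``grid``).  Requires the daily instance to carry its deformation — there
    is deliberately no image-registration fallback.
    """
    if daily.deformation is None:
        raise AccumulationError(
            "daily anatomy carries no deformation (reference instance?)")
    pts = reference.grid.voxel_centers()
    daily_pts = daily.deformation.to_daily(pts)
    vals = fraction_dose.grid.sample(daily_pts, order=1, cval=0.0)
    vals = np.maximum(vals, 0.0).reshape(reference.grid.shape)
    return DoseGrid(reference.grid.like(vals),
                    fraction_count_represented=fraction_dose.fraction_count_represented)


def accumulate(mapped_doses: list[DoseGrid], expected_count: int = 21,
               provenance: list | None = None) -> AccumulatedDose:
    """Voxel-wise sum of co-registered mapped fraction doses."""
    if len(mapped_doses) != expected_count:
        raise AccumulationError(
            f"expected {expected_count} fraction doses, got {len(mapped_doses)}")
    g0 = mapped_doses[0].grid
    for d in mapped_doses[1:]:
        if not d.grid.same_geometry(g0):
            raise AccumulationError("fraction doses not co-registered")
    total = np.sum([d.values for d in mapped_doses], axis=0)
    dose = DoseGrid(g0.like(total),
                    fraction_count_represented=len(mapped_doses))
    return AccumulatedDose(dose, len(mapped_doses), provenance or [])
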