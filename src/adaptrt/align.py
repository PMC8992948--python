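"""Daily-to-planning alignment: 6-DOF bone matching, then prostate-center
to isocenter registration.

The clinical protocol first removes the rotational set-up error by rigid
bone matching (bone is rigid, so the recovered transform must invert the
generator's applied set-up error), then translates so the daily prostate's
geometric center lands on the planning isocenter.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.optimize import minimize

from .deformation import RigidTransform
from .phantom import AnatomyInstance


class AlignmentError(RuntimeError):
    pass


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed distance (mm) to the mask surface, negative inside."""
    if not np.any(mask):
        raise AlignmentError("empty mask")
    return (distance_transform_edt(~mask, sampling=spacing)
            - distance_transform_edt(mask, sampling=spacing))


def rigid_align_bone(daily: AnatomyInstance, reference: AnatomyInstance,
                     max_points: int = 1200) -> RigidTransform:
    """Recover the 6-DOF transform (about the planning isocenter) that maps
    the daily bone onto the reference bone.

    Because bone is rigid, the reference signed-distance field evaluated at
    the correctly transformed daily point must equal the daily signed
    distance at that point; the cost is the mean squared mismatch of the two
    fields over daily bone voxels (sharp in all six degrees of freedom,
    unlike plain overlap of a thick shell).  Initialized at the centroid
    offset with zero rotation, refined by Powell search.
    """
    ref_mask = reference.structures["bone"]
    day_mask = daily.structures["bone"]
    if not np.any(ref_mask) or not np.any(day_mask):
        raise AlignmentError("bone mask empty")
    sdf = reference.grid.like(_signed_distance(ref_mask, reference.grid.spacing))
    sdf_daily = daily.grid.like(_signed_distance(day_mask, daily.grid.spacing))

    pts = daily.grid.mask_centers(day_mask)
    if len(pts) > max_points:
        step = int(np.ceil(len(pts) / max_points))
        pts = pts[::step]
    target = sdf_daily.values[day_mask][::step] if len(
        daily.grid.mask_centers(day_mask)) > max_points         else sdf_daily.values[day_mask]
    center = reference.isocenter

    ref_centroid = reference.grid.mask_centers(ref_mask).mean(axis=0)
    t0 = ref_centroid - pts.mean(axis=0)

    def cost(params):
        tr = RigidTransform(params[:3], params[3:], center)
        d = sdf.sample(tr.apply(pts), order=1, mode="nearest") - target
        return float(np.mean(d * d))

    x0 = np.concatenate([np.zeros(3), t0])
    res = minimize(cost, x0, method="Powell",
                   options={"xtol": 2e-4, "ftol": 1e-12, "maxiter": 20000})
    return RigidTransform(res.x[:3], res.x[3:], center)


def align_prostate_center(daily: AnatomyInstance, reference: AnatomyInstance,
                          after: RigidTransform | None = None) -> np.ndarray:
    """Translation (mm) taking the daily prostate centroid — after the bone
    correction ``after`` — onto the planning isocenter."""
    mask = daily.structures["prostate"]
    if not np.any(mask):
        raise AlignmentError("empty prostate mask")
    centroid = daily.grid.mask_centers(mask).mean(axis=0)
    if after is not None:
        centroid = after.apply(centroid[None, :])[0]
    return np.asarray(reference.isocenter, float) - centroid


def align_daily(daily: AnatomyInstance, reference: AnatomyInstance
                ) -> tuple[AnatomyInstance, RigidTransform]:
    """Full clinical alignment: bone matching then prostate centering.

    Returns the couch-corrected daily anatomy (masks/HU re-evaluated through
    the exact analytic chain — no resampling blur) and the applied rigid
    correction.
    """
    bone = rigid_align_bone(daily, reference)
    shift = align_prostate_center(daily, reference, after=bone)
    correction = RigidTransform(np.zeros(3), shift,
                                reference.isocenter).compose(bone)
    return daily.with_alignment(correction), correction
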