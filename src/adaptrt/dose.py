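"""Spot-scanning proton dose calculation on voxel grids.

Dose at a voxel is the RBE factor (constant 1.1) times the sum over spots of
weight x Bragg depth-dose at the voxel's water-equivalent depth x a
normalized 2-D lateral Gaussian.  Water-equivalent path length (WEPL) is the
line integral of relative stopping power along the (axis-aligned, parallel)
beam direction.  Robustness scenarios enter as a rigid isocenter shift
(dose sampled at shifted positions) and a multiplicative range/RSP scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beam import FIELD_DIRECTIONS, N_FIELDS, BeamModel, SpotPlan, bragg_depth_dose
from .grids import VoxelGrid

RBE = 1.1


@dataclass
class Scenario:
    """One robustness condition: rigid isocenter shift + range scale."""

    shift_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    range_scale: float = 1.0

    def __post_init__(self):
        self.shift_mm = np.asarray(self.shift_mm, float)

    @staticmethod
    def nominal() -> "Scenario":
        return Scenario()

    @property
    def is_nominal(self) -> bool:
        return self.range_scale == 1.0 and not np.any(self.shift_mm)

    def __repr__(self):
        return (f"Scenario(shift={self.shift_mm.tolist()} mm, "
                f"range_scale={self.range_scale})")


@dataclass
class DoseGrid:
    """RBE-weighted dose in Gy(RBE).  ``fraction_count_represented`` records
    whether the grid holds one fraction or a full course."""

    grid: VoxelGrid
    rbe_factor: float = RBE
    fraction_count_represented: int = 21

    def __post_init__(self):
        if np.any(self.grid.values < -1e-9):
            raise ValueError("dose must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def scaled(self, factor: float, fraction_count: int | None = None) -> "DoseGrid":
        return DoseGrid(self.grid.like(self.grid.values * factor),
                        self.rbe_factor,
                        fraction_count if fraction_count is not None
                        else self.fraction_count_represented)


def trace_wepl(rsp: VoxelGrid, entry_point, direction, sample_depths) -> np.ndarray:
    """WEPL(d) = integral of RSP along a ray, by exact voxel-boundary
    traversal (Siddon-style).

    Returns the WEPL at each requested geometric depth; empty array if the
    ray misses the grid.
    """
    p0 = np.asarray(entry_point, float)
    u = np.asarray(direction, float)
    if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-6):
        raise ValueError("direction must be a unit vector")
    depths = np.asarray(sample_depths, float)
    # grid boundary planes (voxel faces)
    lo = rsp.origin - rsp.spacing / 2
    hi = rsp.origin + (np.array(rsp.shape) - 0.5) * rsp.spacing
    # ray-box intersection
    with np.errstate(divide="ignore"):
        t1 = np.where(u != 0, (lo - p0) / u, -np.inf)
        t2 = np.where(u != 0, (hi - p0) / u, np.inf)
    t_lo, t_hi = np.minimum(t1, t2), np.maximum(t1, t2)
    for a in range(3):
        if u[a] == 0 and not (lo[a] <= p0[a] <= hi[a]):
            return np.array([])
    t_enter = max(t_lo.max(), 0.0)
    t_exit = t_hi.min()
    if t_exit <= t_enter:
        return np.array([])

    # all voxel-face crossings inside [t_enter, t_exit]
    ts = [np.array([t_enter, t_exit])]
    for a in range(3):
        if u[a] == 0:
            continue
        planes = lo[a] + rsp.spacing[a] * np.arange(rsp.shape[a] + 1)
        t = (planes - p0[a]) / u[a]
        ts.append(t[(t > t_enter) & (t < t_exit)])
    t_all = np.unique(np.concatenate(ts))
    t_mid = 0.5 * (t_all[:-1] + t_all[1:])
    seg = np.diff(t_all)
    idx = np.clip(np.round(rsp.world_to_continuous_index(
        p0 + t_mid[:, None] * u)).astype(int), 0,
        np.array(rsp.shape) - 1)
    seg_rsp = rsp.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    cum = np.concatenate([[0.0], np.cumsum(seg * seg_rsp)])
    # WEPL at geometric depth d (distance along ray from entry_point)
    return np.interp(depths, t_all, cum, left=0.0, right=cum[-1])


def wepl_grid(rsp: VoxelGrid, field_id: int) -> VoxelGrid:
    """WEPL at every voxel center for an axis-aligned lateral field, via a
    cumulative midpoint sum of RSP along the beam axis."""
    dx = rsp.spacing[0]
    vals = rsp.values
    if field_id == 1:
        vals = vals[::-1, :, :]
    cum = np.cumsum(vals, axis=0) * dx - 0.5 * vals * dx
    if field_id == 1:
        cum = cum[::-1, :, :]
    return rsp.like(cum)


class WeplSampler:
    """Per-field WEPL lookup at arbitrary world points for one anatomy."""

    def __init__(self, rsp: VoxelGrid):
        self.rsp = rsp
        self._grids = [wepl_grid(rsp, f) for f in range(N_FIELDS)]

    def __call__(self, field_id: int, pts: np.ndarray) -> np.ndarray:
        return self._grids[field_id].sample(pts, order=1, mode="nearest")


def dose_at_points(plan: SpotPlan, wepl: WeplSampler, pts: np.ndarray,
                   scenario: Scenario | None = None,
                   dtype=np.float64) -> np.ndarray:
    """Total plan dose in Gy(RBE) at arbitrary world points (dense over
    spots; used for small point sets and the influence matrix)."""
    infl = influence_matrix(plan, wepl, pts, scenario, dtype=dtype)
    return infl @ plan.weight.astype(dtype)


def influence_matrix(plan: SpotPlan, wepl: WeplSampler, pts: np.ndarray,
                     scenario: Scenario | None = None,
                     dtype=np.float32) -> np.ndarray:
    """(n_points, n_spots) matrix of Gy(RBE) per unit spot weight."""
    sc = scenario or Scenario.nominal()
    pts = np.asarray(pts, float)
    shifted = pts + sc.shift_mm
    bm = plan.beam_model
    out = np.zeros((len(pts), plan.n_spots), dtype=dtype)
    for fid in range(N_FIELDS):
        cols = np.flatnonzero(plan.field_id == fid)
        if len(cols) == 0:
            continue
        w = (wepl(fid, shifted) * sc.range_scale).astype(dtype)
        r = plan.range_mm[cols].astype(dtype)
        b = bragg_depth_dose(r[None, :], w[:, None], bm)
        sigma = bm.sigma_at(w)[:, None]
        dy = (shifted[:, 1][:, None] - plan.y_mm[cols][None, :]).astype(dtype)
        dz = (shifted[:, 2][:, None] - plan.z_mm[cols][None, :]).astype(dtype)
        g = np.exp(-0.5 * (dy * dy + dz * dz) / (sigma * sigma)) \
            / (2.0 * np.pi * sigma * sigma)
        out[:, cols] = (RBE * b * g).astype(dtype)
    return out


def compute_dose(plan: SpotPlan, anatomy, scenario: Scenario | None = None,
                 eval_grid: VoxelGrid | None = None,
                 wepl: WeplSampler | None = None) -> DoseGrid:
    """Compute the plan's dose distribution on a grid.

    Parameters
    ----------
    anatomy : AnatomyInstance or VoxelGrid
        Anatomy (HU) or a precomputed RSP grid.
    eval_grid : VoxelGrid, optional
        Evaluation grid; defaults to the anatomy grid.
    wepl : WeplSampler, optional
        Reuse a precomputed WEPL sampler (must match the anatomy).
    """
    sc = scenario or Scenario.nominal()
    if wepl is None:
        rsp = anatomy.rsp if hasattr(anatomy, "rsp") else anatomy
        wepl = WeplSampler(rsp)
    grid = eval_grid if eval_grid is not None else wepl.rsp
    bm = plan.beam_model

    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    dose = np.zeros(grid.shape)
    if plan.n_spots == 0:
        return DoseGrid(grid.like(dose),
                        fraction_count_represented=plan.n_fractions)

    # WEPL of the whole evaluation grid sampled once per field (at the
    # scenario-shifted positions); spots then reuse slices of it
    centers = grid.voxel_centers() + sc.shift_mm
    wepl_box = {}
    sigma_box = {}
    for fid in range(N_FIELDS):
        if np.any(plan.field_id == fid):
            w = (wepl(fid, centers) * sc.range_scale).reshape(grid.shape)
            wepl_box[fid] = w
            sigma_box[fid] = bm.sigma_at(w)

    # per-spot lateral sub-box accumulation
    for i in range(plan.n_spots):
        fid = int(plan.field_id[i])
        r = plan.range_mm[i]
        wgt = plan.weight[i]
        if wgt == 0.0:
            continue
        half = 3.5 * bm.sigma_at(r + bm.distal_cutoff_mm)
        j0, j1 = np.searchsorted(ys, [plan.y_mm[i] - half, plan.y_mm[i] + half])
        k0, k1 = np.searchsorted(zs, [plan.z_mm[i] - half, plan.z_mm[i] + half])
        if j0 == j1 or k0 == k1:
            continue
        w = wepl_box[fid][:, j0:j1, k0:k1]
        b = bragg_depth_dose(r, w, bm)
        sigma = sigma_box[fid][:, j0:j1, k0:k1]
        dy = ys[j0:j1] + sc.shift_mm[1] - plan.y_mm[i]
        dz = zs[k0:k1] + sc.shift_mm[2] - plan.z_mm[i]
        r2 = (dy * dy)[:, None] + (dz * dz)[None, :]
        g = np.exp(-0.5 * r2[None, :, :] / (sigma * sigma)) \
            / (2.0 * np.pi * sigma * sigma)
        dose[:, j0:j1, k0:k1] += wgt * b * g

    return DoseGrid(grid.like(RBE * dose),
                    fraction_count_represented=plan.n_fractions)
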