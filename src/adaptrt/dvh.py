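"""Cumulative dose-volume histograms and DVH indices.

Dq is the minimum dose received by q% of a structure (dose at which the
cumulative curve crosses q/100, linearly interpolated between bins); Vx is
the volume receiving at least x Gy(RBE), relative (%) or absolute (ml).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose import DoseGrid


@dataclass
class DVHCurve:
    """Cumulative DVH: ``volume_fraction[i]`` is the fraction of the
    structure receiving at least ``dose_edges[i]`` Gy(RBE)."""

    structure: str
    dose_edges: np.ndarray
    volume_fraction: np.ndarray
    volume_ml: float

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        ax.plot(self.dose_edges, 100.0 * self.volume_fraction,
                label=self.structure, **kwargs)
        ax.set_xlabel("dose [Gy(RBE)]")
        ax.set_ylabel("volume [%]")
        return ax


def compute_dvh(dose: DoseGrid, mask: np.ndarray, bin_width: float = 0.05,
                structure: str = "") -> DVHCurve:
    """Cumulative DVH of the voxel doses inside a mask."""
    if not np.any(mask):
        raise ValueError("empty structure mask")
    if mask.shape != dose.values.shape:
        raise ValueError("mask and dose grid shapes differ")
    d = dose.values[mask]
    n = d.size
    top = max(float(d.max()), bin_width)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    counts, _ = np.histogram(d, bins=np.append(edges, np.inf))
    # fraction with dose >= edge
    ge = 1.0 - np.concatenate([[0], np.cumsum(counts[:-1])]) / n
    volume_ml = n * dose.grid.voxel_volume / 1000.0
    return DVHCurve(structure, edges, ge, volume_ml)


def dvh_index_d(dvh: DVHCurve, volume_pct: float) -> float:
    """D_q in Gy(RBE): dose at which the cumulative curve crosses q%."""
    if not (0.0 < volume_pct <= 100.0):
        raise ValueError("volume_pct must be in (0, 100]")
    q = volume_pct / 100.0
    v = dvh.volume_fraction
    e = dvh.dose_edges
    # v is non-increasing; find the last edge with v >= q
    idx = np.flatnonzero(v >= q)
    if len(idx) == 0:
        return 0.0
    i = idx[-1]
    if i + 1 >= len(v) or v[i] == v[i + 1]:
        return float(e[i])
    # linear interpolation inside the bin
    frac = (v[i] - q) / (v[i] - v[i + 1])
    return float(e[i] + frac * (e[i + 1] - e[i]))


def dvh_index_v(dvh: DVHCurve, threshold_gy: float,
                absolute: bool = False) -> float:
    """V_x: fractional volume at a dose threshold, in % (default) or ml."""
    if threshold_gy < 0:
        raise ValueError("threshold must be >= 0")
    frac = float(np.interp(threshold_gy, dvh.dose_edges, dvh.volume_fraction,
                           right=0.0))
    return frac * dvh.volume_ml if absolute else 100.0 * frac


def dose_max(dose: DoseGrid, mask: np.ndarray) -> float:
    if not np.any(mask):
        raise ValueError("empty structure mask")
    return float(dose.values[mask].max())
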