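"""PDFF maps, ROI statistics and agreement metrics.

The proton density fat fraction is computed voxelwise from the separated
magnitude images,

.. math:: \\mathrm{PDFF} = \\frac{|F|}{|W| + |F|},

a magnitude formulation that projects every value into [0, 1] and is
robust against residual phase errors, at the price of a positive noise
bias at very low (and negative bias at very high) fat fractions. Agreement
between measured PDFF and known volume fat fractions is summarized by the
mean absolute error (MAE, percentage points), an ordinary least-squares
regression with its coefficient of determination, and Spearman's rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RoiSpec", "pdff_map", "roi_stats", "mae", "agreement"]


@dataclass
class RoiSpec:
    """A named region of interest given as a boolean mask."""

    name: str
    mask: np.ndarray

    def __post_init__(self):
        if self.mask.dtype != bool:
            raise ValueError("ROI mask must be boolean")
        if not np.any(self.mask):
            raise ValueError(f"ROI {self.name!r} is empty")


def pdff_map(fat_mag: np.ndarray, water_mag: np.ndarray, signed_fat: np.ndarray | None = None):
    """Magnitude PDFF map with a flag plane for zero-signal voxels.

    Returns ``(pdff, undefined)``: where ``|W| + |F| = 0`` the PDFF is set
    to 0 and the voxel flagged. Passing ``signed_fat`` (a real fat
    component that may be negative) switches to the complex-valued signed
    definition ``F / (W + F)``, which is *not* confined to [0, 1]; the
    magnitude definition is the default because of its robustness to phase
    errors.
    """
    if fat_mag.shape != water_mag.shape:
        raise ValueError("maps must share a grid")
    if signed_fat is None:
        if np.any(fat_mag < 0) or np.any(water_mag < 0):
            raise ValueError("magnitude maps must be non-negative")
        total = fat_mag + water_mag
        undefined = total == 0
        pdff = np.divide(fat_mag, total, out=np.zeros_like(total, dtype=float),
                         where=~undefined)
        return pdff, undefined
    total = water_mag + signed_fat
    undefined = total == 0
    pdff = np.divide(signed_fat, total, out=np.zeros_like(total, dtype=float),
                     where=~undefined)
    return pdff, undefined


def roi_stats(map_: np.ndarray, rois) -> pd.DataFrame:
    """Mean, population SD and voxel count of a map within each ROI.

    ROIs may not overlap within one evaluation set.
    """
    rois = list(rois)
    taken = np.zeros(map_.shape, dtype=bool)
    for roi in rois:
        if roi.mask.shape != map_.shape:
            raise ValueError(f"ROI {roi.name!r} grid mismatch")
        if np.any(taken & roi.mask):
            raise ValueError(f"ROI {roi.name!r} overlaps a previous ROI")
        taken |= roi.mask
    rows = [
        {
            "name": roi.name,
            "mean": float(np.mean(map_[roi.mask])),
            "sd": float(np.std(map_[roi.mask])),  # population SD
            "n_voxels": int(np.count_nonzero(roi.mask)),
        }
        for roi in rois
    ]
    return pd.DataFrame(rows)


def mae(vff, pdff) -> float:
    """Mean absolute error between reference and measured fat fractions.

    ``(1/K) sum_k |VFF_k - PDFF_k|``, with inputs as fractions and the
    result in percentage points. Invariant to the ordering of the vials.
    """
    vff = np.asarray(vff, dtype=float)
    pdff = np.asarray(pdff, dtype=float)
    if vff.shape != pdff.shape or vff.ndim != 1 or vff.size == 0:
        raise ValueError("vff and pdff must be equal-length non-empty vectors")
    return float(np.mean(np.abs(vff - pdff))) * 100.0


def agreement(vff, pdff) -> dict:
    """Linear agreement between reference and measured fat fractions.

    Ordinary least-squares regression of PDFF on VFF (slope, intercept,
    R^2 of the fit) plus Spearman's rank correlation (average ranks for
    ties). For identical vectors: R^2 = 1, slope 1, intercept 0, rho 1.
    """
    vff = np.asarray(vff, dtype=float)
    pdff = np.asarray(pdff, dtype=float)
    if vff.shape != pdff.shape or vff.size < 2:
        raise ValueError("need at least two paired values")
    fit = stats.linregress(vff, pdff)
    rho = stats.spearmanr(vff, pdff).statistic
    return {
        "r_squared": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "spearman_rho": float(rho),
    }
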