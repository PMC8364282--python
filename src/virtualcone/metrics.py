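"""Dose metrics on anatomy-fixed spherical targets and shells.

Plans are normalized so that the prescription dose (100%) covers 99% of
the target volume in the no-motion delivery (D_99 normalization); the same
scale factor — i.e. the same monitor units — is applied to the matching
motion delivery without re-derivation.  All D_x values are exact
voxel-count quantiles (no DVH binning): D_x is the largest dose level
received by at least x% of the structure volume, so D_m (x = 100) is the
in-structure minimum.  V_x is the volume (cc) receiving at least x% of
the prescription.

Conformity degradation under motion is quantified by the ratio of Paddick
conformity indices,

    R_C = (TV_M² / PIV_M) / (TV_NO² / PIV_NO),

with TV the target volume covered by the prescription isodose and PIV the
prescription isodose volume, both evaluated at the *no-motion*
prescription level.  Dose-falloff steepness is the gradient index
GI = V_50 / V_100.  The prescription isodose volume counts every voxel at
or above the prescription anywhere in the grid (no connected-component
filtering), since motion can split the isodose surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import DoseGrid, sphere_mask


@dataclass(frozen=True)
class TargetSpec:
    """A centered spherical target with concentric 1-mm evaluation shells."""

    diameter: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shell_thickness: float = 1.0
    n_shells: int = 3

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("target diameter must be positive")
        if self.shell_thickness <= 0 or self.n_shells < 0:
            raise ValueError("invalid shell specification")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def target_mask(self, grid: DoseGrid) -> np.ndarray:
        return sphere_mask(grid, self.diameter, self.center)

    def shell_mask(self, grid: DoseGrid, index: int) -> np.ndarray:
        """Mask of the ``index``-th (1-based) 1-mm annulus abutting the target."""
        if not 1 <= index <= self.n_shells:
            raise ValueError("shell index out of range")
        outer_d = self.diameter + 2.0 * index * self.shell_thickness
        inner_d = outer_d - 2.0 * self.shell_thickness
        return sphere_mask(grid, outer_d, self.center) \
            & ~sphere_mask(grid, inner_d, self.center)

    def shell_masks(self, grid: DoseGrid) -> list[np.ndarray]:
        return [self.shell_mask(grid, i) for i in range(1, self.n_shells + 1)]


def _structure_values(dose: DoseGrid | np.ndarray,
                      mask: np.ndarray | None) -> np.ndarray:
    vals = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    vals = vals[mask] if mask is not None else vals.reshape(-1)
    if vals.size == 0:
        raise ValueError("structure mask is empty")
    return vals


def dose_at_volume(dose: DoseGrid | np.ndarray, mask: np.ndarray | None,
                   x: float) -> float:
    """D_x: the largest dose level received by at least x% of the structure."""
    if not 0.0 < x <= 100.0:
        raise ValueError("x must lie in (0, 100]")
    vals = np.sort(_structure_values(dose, mask))[::-1]
    k = math.ceil(x / 100.0 * vals.size)
    return float(vals[k - 1])


def volume_at_dose(dose: DoseGrid, x: float,
                   region: np.ndarray | None = None) -> float:
    """V_x: volume (cc) receiving at least x% of the prescription.

    ``dose`` must already be normalized so 100 = prescription.  The region
    defaults to the whole grid.
    """
    vals = dose.values if region is None else dose.values[region]
    return float(np.count_nonzero(vals >= x) * dose.voxel_volume_cc)


def normalize_to_prescription(dose: DoseGrid,
                              target_mask: np.ndarray) -> tuple[DoseGrid, float]:
    """Scale so the prescription (100) covers 99% of the target (D_99).

    Returns the scaled grid and the scale factor; apply the *same* factor
    to the corresponding motion delivery (same MU).
    """
    d99 = dose_at_volume(dose, target_mask, 99.0)
    if d99 <= 0:
        raise ValueError("target D_99 is zero; degenerate plan")
    scale = 100.0 / d99
    return dose.with_values(dose.values * scale), scale


def paddick_ratio(tv_m: float, piv_m: float, tv_no: float, piv_no: float) -> float:
    """Ratio of Paddick conformity indices, motion vs no motion."""
    if tv_no <= 0 or piv_no <= 0:
        raise ValueError("no-motion volumes must be positive")
    if tv_m == 0:
        return 0.0
    if piv_m <= 0:
        raise ValueError("PIV_M must be positive when TV_M > 0")
    return (tv_m ** 2 / piv_m) / (tv_no ** 2 / piv_no)


def gradient_index(dose: DoseGrid, region: np.ndarray | None = None) -> float:
    """GI = V_50 / V_100 on a prescription-normalized dose grid."""
    v100 = volume_at_dose(dose, 100.0, region)
    if v100 <= 0:
        raise ValueError("V_100 is zero; gradient index undefined")
    return volume_at_dose(dose, 50.0, region) / v100


def tv_piv(dose: DoseGrid, target_mask: np.ndarray) -> tuple[float, float]:
    """(TV, PIV) in cc at the prescription level of a normalized grid."""
    tv = volume_at_dose(dose, 100.0, target_mask)
    piv = volume_at_dose(dose, 100.0)
    return tv, piv


def shell_metrics(dose: DoseGrid, target: TargetSpec) -> pd.DataFrame:
    """Per-shell D_m and D_5 (percent of prescription) for the 1-mm annuli."""
    rows = []
    for i in range(1, target.n_shells + 1):
        mask = target.shell_mask(dose, i)
        rows.append({"shell": i,
                     "D_m": dose_at_volume(dose, mask, 100.0),
                     "D_5": dose_at_volume(dose, mask, 5.0)})
    return pd.DataFrame(rows)


def dvh_curve(dose: DoseGrid, mask: np.ndarray,
              bin_width: float = 0.5) -> pd.DataFrame:
    """Cumulative DVH sampled on a regular dose grid (for plotting only)."""
    vals = _structure_values(dose, mask)
    top = max(float(vals.max()), bin_width)
    levels = np.arange(0.0, top + bin_width, bin_width)
    covered = [(vals >= lv).mean() for lv in levels]
    return pd.DataFrame({"dose_pct": levels, "covered_fraction": covered})


def profiles_and_wash(dose: DoseGrid, threshold: float = 50.0) -> dict:
    """Orthogonal-axis dose profiles and per-plane dose-wash areas.

    Returns the 1D profiles along x, y, z through isocenter and, for each
    isocenter plane (axial = x-y, sagittal = y-z, coronal = x-z), the area
    in mm² with dose at or above ``threshold`` (% of prescription).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    c = (dose.n - 1) // 2
    vals = dose.values
    area = dose.voxel_size ** 2
    return {
        "coords_mm": dose.axis_coords(0),
        "profile_x": vals[:, c, c].copy(),
        "profile_y": vals[c, :, c].copy(),
        "profile_z": vals[c, c, :].copy(),
        "wash_area_axial_mm2": float(np.count_nonzero(vals[:, :, c] >= threshold) * area),
        "wash_area_sagittal_mm2": float(np.count_nonzero(vals[c, :, :] >= threshold) * area),
        "wash_area_coronal_mm2": float(np.count_nonzero(vals[:, c, :] >= threshold) * area),
    }


#: Volume levels (% of prescription) reported in the metrics table.
V_LEVELS = (100, 95, 70, 50, 30, 10)
#: Target dose quantiles reported in the metrics table.
D_LEVELS = (5, 95, 99)


def target_dose_summary(dose: DoseGrid, target_mask: np.ndarray) -> dict:
    """Standard D_x/V_x inventory for one normalized dose grid."""
    out = {"D_m": dose_at_volume(dose, target_mask, 100.0),
           "D_max": float(dose.values[target_mask].max())}
    for x in D_LEVELS:
        out[f"D_{x}"] = dose_at_volume(dose, target_mask, float(x))
    for x in V_LEVELS:
        out[f"V_{x}"] = volume_at_dose(dose, float(x))
    return out
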