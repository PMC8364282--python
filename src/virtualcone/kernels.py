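"""Analytic static-beam dose kernels on the spherical water phantom.

The delivery engine superposes rotated copies of a single static-beam dose
kernel.  Here that kernel is synthesized analytically rather than by Monte
Carlo transport: a rectangular MLC fluence with a finite (error-function)
penumbra and beam divergence, multiplied by a depth-dose curve with
exponential buildup and attenuation measured from the ray's entry into the
phantom sphere, and by inverse-square falloff from the source.  The model
captures the statistical structure of a 6 MV FFF small-field beam — sharp
lateral edges, dose buildup, quasi-exponential depth falloff — without
claiming absolute dosimetric accuracy; downstream analyses normalize every
plan to the target's D_99, so only the relative shape matters.

The kernel maximum is normalized to 1 before the final Gaussian smoothing
(sigma 1.2 voxels by default) that mimics the smoothing applied to noisy
Monte Carlo kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy import ndimage
from scipy.special import erf

from .geometry import Aperture, MachineGeometry


@dataclass
class DoseGrid:
    """A cubic 3D scalar dose field with isotropic voxels.

    ``values[i, j, k]`` sits at world coordinate
    ``origin + (index − (n−1)/2) · voxel_size`` so the central voxel of an
    odd-sized grid lies exactly at the grid origin (isocenter by default).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError("DoseGrid requires a cubic 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def half_extent(self) -> float:
        """Distance from grid center to the outer face of an edge voxel, mm."""
        return self.n * self.voxel_size / 2.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size ** 3

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int = 0) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return (np.arange(self.n) - (self.n - 1) / 2.0) * self.voxel_size \
            + self.origin[axis]

    def points(self) -> np.ndarray:
        """All voxel-center world coordinates, shape (3, n³)."""
        axes = [self.axis_coords(a) for a in range(3)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.reshape(-1) for m in mesh], axis=0)

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(values, self.voxel_size, self.origin.copy())

    def copy(self) -> "DoseGrid":
        return self.with_values(self.values.copy())


def make_grid(extent: float, voxel_size: float, dtype=np.float32) -> DoseGrid:
    """An empty odd-sized cubic grid spanning at least ``extent`` mm."""
    half = int(np.ceil(extent / (2.0 * voxel_size)))
    n = 2 * half + 1
    return DoseGrid(np.zeros((n, n, n), dtype=dtype), voxel_size)


def phantom_grid(machine: MachineGeometry, dtype=np.float32,
                 pad_voxels: int = 6) -> DoseGrid:
    """An empty grid spanning the whole phantom sphere.

    A few voxels of zero padding beyond the phantom surface keep every
    nonzero dose value away from the grid boundary, where B-spline
    prefiltering is not exactly interpolating.
    """
    return make_grid(machine.phantom_diameter + 2 * pad_voxels * machine.voxel_size,
                     machine.voxel_size, dtype=dtype)


def sphere_mask(grid: DoseGrid, diameter: float,
                center: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``diameter/2`` of ``center``.

    Raises ``ValueError`` if the sphere does not fit inside the grid.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    center = np.asarray(center, dtype=float)
    radius = diameter / 2.0
    for axis in range(3):
        lo = grid.origin[axis] - grid.half_extent
        hi = grid.origin[axis] + grid.half_extent
        if center[axis] - radius < lo - 1e-9 or center[axis] + radius > hi + 1e-9:
            raise ValueError("sphere exceeds the dose grid")
    x, y, z = (grid.axis_coords(a) - center[a] for a in range(3))
    r2 = (x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2)
    return r2 <= radius ** 2


@dataclass(frozen=True)
class KernelModelParams:
    """Tunable parameters of the analytic kernel model.

    penumbra_sigma_iso:
        Gaussian blur of the fluence edge at the isocenter plane, mm.  This
        lumps source size, MLC transmission gradients, and lateral scatter
        into a single width.
    mu_atten:
        Effective exponential attenuation coefficient, 1/mm (6 MV-like
        water value ≈ 0.0046/mm).
    buildup_beta:
        Electron-buildup rate, 1/mm; depth dose rises as 1 − exp(−β·d)
        (β = 0.35/mm puts d_max near 14 mm, FFF-like).
    smoothing_sigma:
        Gaussian post-filter width in voxels (default 1.2).
    """

    penumbra_sigma_iso: float = 1.0
    mu_atten: float = 0.0046
    buildup_beta: float = 0.35
    smoothing_sigma: float = 1.2

    def __post_init__(self) -> None:
        for name in ("penumbra_sigma_iso", "mu_atten", "buildup_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"KernelModelParams.{name} must be positive")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be non-negative")


def analytic_kernel_values(points: np.ndarray, aperture: Aperture,
                           machine: MachineGeometry,
                           params: KernelModelParams) -> np.ndarray:
    """Evaluate the unsmoothed, unnormalized kernel at world points (3, N).

    Beam along −z through isocenter, source at (0, 0, SAD).  The dose is
    F_x(x, z) · F_y(y, z) · PDD(depth) · ISQ with error-function lateral
    profiles of the diverged field edges, depth measured from the central
    ray's entry into the phantom sphere, and zero outside the sphere.
    """
    pts = np.asarray(points, dtype=np.float64)
    x, y, z = pts[0], pts[1], pts[2]
    sad = machine.sad
    radius = machine.phantom_radius

    # Project each voxel back to the isocenter plane along its ray.
    dz = sad - z
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = sad / dz
    xi = x * scale
    yi = y * scale

    sig = params.penumbra_sigma_iso * np.sqrt(2.0)
    wx = aperture.gap / 2.0
    wy = aperture.n_leaf_pairs * machine.leaf_width_at_iso / 2.0
    fx = 0.5 * (erf((wx - xi) / sig) + erf((wx + xi) / sig))
    fy = 0.5 * (erf((wy - yi) / sig) + erf((wy + yi) / sig))

    # Depth along the ray from the sphere-entry point.
    t_p = np.sqrt(x ** 2 + y ** 2 + dz ** 2)  # source-to-point distance
    b = sad * (z - sad) / t_p                 # = u · S for ray direction u
    disc = b ** 2 - (sad ** 2 - radius ** 2)
    inside = x ** 2 + y ** 2 + z ** 2 <= radius ** 2
    disc = np.where(disc > 0, disc, 0.0)
    t_entry = -b - np.sqrt(disc)
    depth = np.clip(t_p - t_entry, 0.0, None)

    pdd = (1.0 - np.exp(-params.buildup_beta * depth)) * np.exp(-params.mu_atten * depth)
    isq = (sad / t_p) ** 2

    dose = fx * fy * pdd * isq
    dose[~inside] = 0.0
    return np.clip(dose, 0.0, None)


def synthesize_kernel(aperture: Aperture, machine: MachineGeometry,
                      params: KernelModelParams | None = None,
                      grid: DoseGrid | None = None) -> DoseGrid:
    """Sample the analytic kernel on a phantom-spanning grid, max-normalized.

    The returned kernel is unsmoothed; apply :func:`smooth_kernel` (or use
    :func:`make_treatment_kernel`) before delivery.
    """
    params = params or KernelModelParams()
    if grid is None:
        grid = phantom_grid(machine)
    if aperture.gap > grid.half_extent * 2 or aperture.length > grid.half_extent * 2:
        raise ValueError("aperture exceeds the grid cross-section")
    # evaluate in x-slabs to bound the size of float64 temporaries
    n = grid.n
    vals = np.empty((n, n, n), dtype=np.float32)
    xc = grid.axis_coords(0)
    yz = np.meshgrid(grid.axis_coords(1), grid.axis_coords(2), indexing="ij")
    chunk = max(1, int(2e6) // (n * n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        xs = np.repeat(xc[start:stop], n * n)
        pts = np.stack([xs,
                        np.tile(yz[0].ravel(), stop - start),
                        np.tile(yz[1].ravel(), stop - start)])
        vals[start:stop] = analytic_kernel_values(
            pts, aperture, machine, params).reshape(stop - start, n, n)
    peak = vals.max()
    if peak <= 0:
        raise ValueError("kernel evaluated to zero everywhere")
    return grid.with_values((vals / peak).astype(grid.values.dtype))


def smooth_kernel(kernel: DoseGrid, sigma: float = 1.2) -> DoseGrid:
    """Gaussian-smooth a kernel; ``sigma`` is in voxels.  sigma = 0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return kernel.copy()
    sm = ndimage.gaussian_filter(kernel.values, sigma=sigma,
                                 mode="constant", cval=0.0)
    return kernel.with_values(sm)


def make_treatment_kernel(aperture: Aperture, machine: MachineGeometry,
                          params: KernelModelParams | None = None) -> DoseGrid:
    """Synthesized and smoothed kernel ready for the delivery engine."""
    params = params or KernelModelParams()
    return smooth_kernel(synthesize_kernel(aperture, machine, params),
                         params.smoothing_sigma)


def save_nifti(grid: DoseGrid, path) -> None:
    """Write a dose grid as a NIfTI volume with voxel-size metadata."""
    affine = np.eye(4)
    affine[:3, :3] *= grid.voxel_size
    affine[:3, 3] = grid.origin - grid.voxel_size * (grid.n - 1) / 2.0
    nib.save(nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), affine),
             str(path))


def load_nifti(path) -> DoseGrid:
    img = nib.load(str(path))
    vals = np.asarray(img.dataobj, dtype=np.float32)
    affine = img.affine
    voxel = float(affine[0, 0])
    n = vals.shape[0]
    origin = affine[:3, 3] + voxel * (n - 1) / 2.0
    return DoseGrid(vals, voxel, origin)
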