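#!/usr/bin/env python
"""Synthesize representative static-beam dose kernels and characterize them.

For three representative apertures (smallest, mid, largest) at the reduced
0.5-mm preset this writes the smoothed kernel volumes as NIfTI under
results/kernels/ and a CSV of central-axis depth dose and isocenter-plane
lateral profiles.  Printed summary: kernel peak position and the lateral
50%-of-max widths, which should track gap and leaf-stack length.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from virtualcone.geometry import Aperture, MachineGeometry
from virtualcone.kernels import make_treatment_kernel, save_nifti

OUT = Path(__file__).resolve().parents[1] / "results"
APERTURES = [Aperture(1, 1.0), Aperture(2, 4.0), Aperture(4, 10.0)]


def half_max_width(coords, profile):
    half = profile.max() / 2.0
    above = np.flatnonzero(profile >= half)
    return coords[above[-1]] - coords[above[0]]


def main() -> None:
    machine = MachineGeometry(voxel_size=0.5)
    kdir = OUT / "kernels"
    kdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ap in APERTURES:
        kernel = make_treatment_kernel(ap, machine)
        stem = ap.label.replace(" ", "")
        save_nifti(kernel, kdir / f"kernel_{stem}.nii.gz")
        c = (kernel.n - 1) // 2
        coords = kernel.axis_coords(0)
        prof_x = kernel.values[:, c, c]
        prof_y = kernel.values[c, :, c]
        depth = kernel.values[c, c, ::-1]  # entry side first
        pd.DataFrame({"coord_mm": coords, "profile_x": prof_x,
                      "profile_y": prof_y, "depth_dose": depth}).to_csv(
            kdir / f"profiles_{stem}.csv", index=False)
        rows.append({
            "aperture": ap.label,
            "gap_mm": ap.gap,
            "length_mm": ap.length,
            "fwhm_x_mm": half_max_width(coords, prof_x),
            "fwhm_y_mm": half_max_width(coords, prof_y),
            "peak_depth_mm": coords[np.argmax(depth)] + machine.phantom_radius,
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(kdir / "kernel_summary.csv", index=False)
    print(summary.to_string(index=False))
    print("\nLateral 50% widths track the aperture dimensions; the depth-dose"
          "\npeak sits at the buildup depth below the sphere surface.")


if __name__ == "__main__":
    main()
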