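#!/usr/bin/env python
"""No-motion dosimetry of the virtual cone: target vs shell trade-off.

Delivers the static-collimator 3-arc plan for nine representative
apertures to a 5-mm central target at the reduced preset, normalizes each
plan to D_99 = 100%, and tabulates the target D_5 together with D_m/D_5
in the three 1-mm concentric shells.  The expected trade-off: larger
effective apertures flatten the target dose (lower D_5) at the cost of a
higher minimum dose in the surrounding shells.

Writes results/no_motion_shell_metrics.csv and a GI-per-aperture table.
"""

import logging
from pathlib import Path

from virtualcone.geometry import Aperture
from virtualcone.experiments import RunConfig, run_grid

OUT = Path(__file__).resolve().parents[1] / "results"

# the aperture columns of the 5-mm-target dose-metrics table
APERTURES = [Aperture(1, 1.0), Aperture(2, 1.0), Aperture(2, 3.0),
             Aperture(2, 5.0), Aperture(3, 3.0), Aperture(3, 5.0),
             Aperture(3, 7.0), Aperture(4, 2.0), Aperture(4, 6.0)]

COLUMNS = ["aperture", "effective_area_cm2", "D_5",
           "shell1_D_m", "shell1_D_5", "shell2_D_m", "shell2_D_5",
           "shell3_D_m", "shell3_D_5", "GI", "D_max", "feasible"]


def main() -> None:
    logging.basicConfig(level=logging.INFO)
    OUT.mkdir(exist_ok=True)
    cfg = RunConfig(apertures=tuple(APERTURES), target_diameters=(5.0,),
                    collimator_modes=("static",), trace_names=(),
                    preset="reduced")
    df = run_grid(cfg, progress=True)
    table = (df[df["trace"] == "none"][COLUMNS]
             .sort_values("effective_area_cm2")
             .round({c: 1 for c in COLUMNS if c.startswith(("D", "shell", "G"))}))
    table.to_csv(OUT / "no_motion_shell_metrics.csv", index=False)
    print(table.to_string(index=False))
    print("\nLarger apertures: target D_5 falls, shell D_m rises "
          "(gentler gradient); GI grows with effective area.")


if __name__ == "__main__":
    main()
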