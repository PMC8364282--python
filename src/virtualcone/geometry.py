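"""Machine geometry, MLC aperture catalogue, and arc-plan construction.

A "virtual cone" treatment shapes a near-spherical dose distribution by
sweeping a small rectangular MLC aperture over three arcs (one 360° axial
arc and two 180° oblique arcs with the couch at ±45°) while varying the
collimator angle, either by delivering every arc twice at collimator ±45°
(*static* mode) or by rotating the collimator 180° within each arc
(*dynamic* mode).

Angle conventions (fixed right-handed room frame):

* beam travels along −z at gantry 0° (source on +z);
* gantry rotates about the room y-axis;
* couch rotates about the room z-axis through isocenter;
* collimator rotates about the beam axis.

All reported dose metrics on the centered spherical phantom are invariant
to this convention choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Width of a central HDMLC leaf pair projected to isocenter (mm).
LEAF_WIDTH_MM = 2.5


@dataclass(frozen=True)
class MachineGeometry:
    """Linac and phantom geometry.

    Parameters
    ----------
    sad:
        Source-axis distance in mm.
    leaf_width_at_iso:
        MLC leaf width projected to the isocenter plane, mm.
    phantom_diameter:
        Diameter of the water-sphere phantom, mm.
    voxel_size:
        Isotropic dose-grid voxel edge, mm.  0.25 mm is the full-resolution
        setting; routine work uses the 0.5-mm reduced preset.
    """

    sad: float = 1000.0
    leaf_width_at_iso: float = LEAF_WIDTH_MM
    phantom_diameter: float = 82.0
    voxel_size: float = 0.25

    def __post_init__(self) -> None:
        for name in ("sad", "leaf_width_at_iso", "phantom_diameter", "voxel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MachineGeometry.{name} must be strictly positive")

    @property
    def phantom_radius(self) -> float:
        return self.phantom_diameter / 2.0


def effective_area(n_leaf_pairs: int, gap: float,
                   leaf_width_at_iso: float = LEAF_WIDTH_MM) -> float:
    """Effective open area of an MLC aperture, in cm².

    The aperture is ``n_leaf_pairs`` adjacent leaf pairs, each
    ``leaf_width_at_iso`` mm wide, opened to an across-leaf ``gap`` (mm):
    area = n × 2.5 mm × gap.
    """
    if n_leaf_pairs < 1 or int(n_leaf_pairs) != n_leaf_pairs:
        raise ValueError("n_leaf_pairs must be a positive integer")
    if gap <= 0:
        raise ValueError("gap must be strictly positive")
    if leaf_width_at_iso <= 0:
        raise ValueError("leaf_width_at_iso must be strictly positive")
    return n_leaf_pairs * leaf_width_at_iso * gap / 100.0  # mm² -> cm²


@dataclass(frozen=True)
class Aperture:
    """A rectangular MLC-shaped opening: ``n_leaf_pairs`` × ``gap`` mm.

    The across-leaf opening (``gap``) lies along x in the beam frame; the
    leaf stack (length ``n_leaf_pairs × 2.5 mm``) lies along y.  Labels
    follow the clinical "gap × length mm²" convention, e.g. 2 leaf pairs
    with a 2-mm gap is ``"2 x 5 mm2"``.
    """

    n_leaf_pairs: int
    gap: float

    def __post_init__(self) -> None:
        if not (1 <= self.n_leaf_pairs <= 4):
            raise ValueError("n_leaf_pairs must be in 1..4")
        if self.gap <= 0:
            raise ValueError("gap must be strictly positive")

    @property
    def length(self) -> float:
        """Along-leaf-stack field dimension at isocenter, mm."""
        return self.n_leaf_pairs * LEAF_WIDTH_MM

    @property
    def effective_area_cm2(self) -> float:
        return effective_area(self.n_leaf_pairs, self.gap)

    @property
    def label(self) -> str:
        return f"{self.gap:g} x {self.length:g} mm2"


def _build_catalogue() -> tuple[Aperture, ...]:
    gaps_by_pairs = {1: (1, 2, 3), 2: (1, 2, 3, 4, 5),
                     3: (2, 3, 4, 5, 6, 7), 4: (2, 4, 6, 8, 10)}
    return tuple(Aperture(n, float(g))
                 for n, gaps in gaps_by_pairs.items() for g in gaps)


#: The 19 catalogued treatment apertures (1 x 2.5 mm² up to 10 x 10 mm²).
APERTURE_CATALOGUE: tuple[Aperture, ...] = _build_catalogue()


def catalogue_frame() -> pd.DataFrame:
    """The aperture catalogue as a tidy table (one row per aperture)."""
    return pd.DataFrame(
        {
            "leaf_pairs": [a.n_leaf_pairs for a in APERTURE_CATALOGUE],
            "gap_mm": [a.gap for a in APERTURE_CATALOGUE],
            "effective_area_cm2": [a.effective_area_cm2 for a in APERTURE_CATALOGUE],
            "label": [a.label for a in APERTURE_CATALOGUE],
        }
    )


def aperture_by_label(label: str) -> Aperture:
    for a in APERTURE_CATALOGUE:
        if a.label == label:
            return a
    raise KeyError(f"no catalogued aperture labelled {label!r}")


@dataclass(frozen=True)
class ArcSpec:
    """One gantry arc at a fixed couch angle.

    The gantry span must be 180° or 360° and the control-point spacing
    must divide it.
    """

    couch_angle: float
    gantry_start: float
    gantry_stop: float
    control_point_spacing: float = 10.0

    def __post_init__(self) -> None:
        span = abs(self.gantry_stop - self.gantry_start)
        if span not in (180.0, 360.0):
            raise ValueError("gantry span must be 180 or 360 degrees")
        if self.control_point_spacing <= 0:
            raise ValueError("control_point_spacing must be positive")
        n = span / self.control_point_spacing
        if abs(n - round(n)) > 1e-9:
            raise ValueError("control_point_spacing must divide the gantry span")

    @property
    def span(self) -> float:
        return abs(self.gantry_stop - self.gantry_start)

    @property
    def n_control_points(self) -> int:
        return int(round(self.span / self.control_point_spacing))


def default_arcs(spacing: float = 10.0) -> tuple[ArcSpec, ...]:
    """The standard 3-arc set: axial 360° plus two 180° obliques at couch ±45°."""
    return (
        ArcSpec(0.0, 0.0, 360.0, spacing),
        ArcSpec(45.0, 0.0, 180.0, spacing),
        ArcSpec(-45.0, 0.0, 180.0, spacing),
    )


@dataclass(frozen=True)
class ControlPoint:
    """One delivery instant: machine angles plus fractional time and MU weight."""

    gantry: float
    couch: float
    collimator: float
    t: float
    weight: float


def dynamic_collimator_angle(arc: ArcSpec, frac: float) -> float:
    """Collimator angle at arc fraction ``frac`` in dynamic mode.

    The collimator sweeps 180° within each arc.  The 360° axial arc uses a
    triangular pattern (0°→180° over the first half, 180°→0° over the
    second); the 180° oblique arcs sweep linearly 0°→180°.
    """
    if not 0.0 <= frac <= 1.0:
        raise ValueError("arc fraction must lie in [0, 1]")
    if arc.span == 360.0:
        return 360.0 * frac if frac <= 0.5 else 360.0 * (1.0 - frac)
    return 180.0 * frac


@dataclass(frozen=True)
class PlanSpec:
    """An ordered control-point sequence for one aperture and collimator mode."""

    aperture: Aperture
    collimator_mode: str
    control_points: tuple[ControlPoint, ...]
    arcs: tuple[ArcSpec, ...] = field(default_factory=default_arcs)

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    def to_config(self) -> dict:
        """Plan specification as a plain dictionary (YAML-serializable)."""
        return {
            "aperture": {"leaf_pairs": self.aperture.n_leaf_pairs,
                         "gap_mm": self.aperture.gap},
            "collimator_mode": self.collimator_mode,
            "arcs": [
                {"couch_angle": a.couch_angle, "gantry_start": a.gantry_start,
                 "gantry_stop": a.gantry_stop,
                 "spacing": a.control_point_spacing}
                for a in self.arcs
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_config(), sort_keys=False)


def plan_from_config(config: dict) -> "PlanSpec":
    """Rebuild a plan from the dictionary produced by :meth:`PlanSpec.to_config`."""
    ap = Aperture(config["aperture"]["leaf_pairs"], config["aperture"]["gap_mm"])
    arcs = tuple(
        ArcSpec(a["couch_angle"], a["gantry_start"], a["gantry_stop"],
                a.get("spacing", 10.0))
        for a in config["arcs"]
    )
    return build_arc_plan(ap, config["collimator_mode"], arcs)


def plan_table(plan: PlanSpec) -> pd.DataFrame:
    """Per-control-point debug table: angles, fractional time, MU weight."""
    return pd.DataFrame(
        {
            "gantry": [cp.gantry for cp in plan.control_points],
            "couch": [cp.couch for cp in plan.control_points],
            "collimator": [cp.collimator for cp in plan.control_points],
            "t": [cp.t for cp in plan.control_points],
            "weight": [cp.weight for cp in plan.control_points],
        }
    )


def build_arc_plan(aperture: Aperture, collimator_mode: str,
                   arcs: tuple[ArcSpec, ...] | None = None,
                   machine: MachineGeometry | None = None) -> PlanSpec:
    """Turn a prescription into an ordered control-point sequence.

    Gantry angles are sampled at the midpoints of the 10° control-point
    bins (5°, 15°, …), which avoids double-weighting the axial arc's
    shared 0°/360° endpoint: the default arcs give 36 + 18 + 18 = 72
    geometric points.  In dynamic mode each point appears once with the
    collimator swept per :func:`dynamic_collimator_angle`; in static mode
    each arc is delivered twice, at collimator +45° and −45° (144 points
    total).  Delivery order is axial arc, couch +45°, couch −45°, with
    each static pass completing before the next begins; ``t`` advances
    uniformly per control point and MU weights are uniform, summing to 1.
    """
    if collimator_mode not in ("static", "dynamic"):
        raise ValueError("collimator_mode must be 'static' or 'dynamic'")
    if arcs is None:
        arcs = default_arcs()
    arcs = tuple(arcs)

    sequence: list[tuple[float, float, float]] = []  # (gantry, couch, collimator)
    for arc in arcs:
        n = arc.n_control_points
        direction = 1.0 if arc.gantry_stop >= arc.gantry_start else -1.0
        fracs = (np.arange(n) + 0.5) / n
        gantries = arc.gantry_start + direction * fracs * arc.span
        if collimator_mode == "dynamic":
            colls = [dynamic_collimator_angle(arc, f) for f in fracs]
            sequence.extend(zip(gantries, [arc.couch_angle] * n, colls))
        else:
            for coll in (45.0, -45.0):
                sequence.extend(zip(gantries, [arc.couch_angle] * n, [coll] * n))

    n_total = len(sequence)
    cps = tuple(
        ControlPoint(gantry=float(g), couch=float(c), collimator=float(k),
                     t=(i + 0.5) / n_total, weight=1.0 / n_total)
        for i, (g, c, k) in enumerate(sequence)
    )
    return PlanSpec(aperture=aperture, collimator_mode=collimator_mode,
                    control_points=cps, arcs=arcs)
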