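# Methods

`virtualcone` simulates stereotactic-radiosurgery "virtual cone"
deliveries — near-spherical dose distributions shaped by sweeping a small
rectangular MLC aperture over arcs at multiple collimator angles — and
quantifies how intrafraction patient motion degrades their dosimetry.
This note records the model, its assumptions, the parameters that matter,
and what the synthetic pieces do and do not establish.

## Delivery model

A treatment is three arcs around an 8.2-cm-diameter water sphere with the
target at isocenter: one 360° axial arc (couch 0°) and two 180° arcs with
the couch at ±45°.  Each arc is discretized into control points every 10°
of gantry rotation, sampled at the bin midpoints (5°, 15°, …) so the
axial arc's shared 0°/360° endpoint is not double-weighted: 36 + 18 + 18
= 72 geometric points.  The virtual cone is formed in one of two ways:

* **static collimator** — every arc is delivered twice, at collimator
  +45° and −45° (144 control points);
* **dynamic collimator** — each arc is delivered once while the
  collimator sweeps 180°; the axial arc uses a triangular 0°→180°→0°
  pattern, the obliques a linear 0°→180°.

MU weights are uniform and sum to one; fractional treatment time `t`
advances uniformly in delivery order (axial arc first, then couch +45°,
then couch −45°, each static pass completing before the next).  The
oblique arcs' gantry range is not uniquely determined by the arc
geometry; both run 0°→180° by default and are configurable.  Whether the
static ±45° passes each carry half or full MU is immaterial because the
total is normalized to one.

Plan dose is the weighted superposition of the static-beam kernel rotated
to each control point's orientation.  Rotations compose as collimator
(about the beam axis), then gantry (about the room y-axis), then couch
(about the room z-axis); beam travel is −z at gantry 0°.  On the
centered spherical phantom all reported metrics are invariant to this
convention.  Resampling is tricubic (cubic B-spline) interpolation with
the spline prefilter computed once per kernel; out-of-grid points read
zero and negative overshoots are clamped to zero.  Kernel grids are
padded six voxels beyond the phantom surface because constant-mode
B-spline prefiltering is not exactly interpolating at the array boundary.

## Synthetic kernel

The static-beam kernel is analytic rather than Monte Carlo:

    dose(x, y, z) = F_x(x, z) · F_y(y, z) · PDD(d) · (SAD / r)²

with error-function lateral profiles of the diverged rectangular field
(edge blur `penumbra_sigma_iso`, scaled with distance from the source),
depth dose `PDD(d) = (1 − e^(−β d)) · e^(−μ d)` measured from the central
ray's entry into the sphere, inverse-square falloff, zero dose outside
the phantom, per-kernel maximum normalized to 1, and a final Gaussian
smoothing of 1.2 voxels (the same filter one applies to noisy Monte
Carlo kernels).

Defaults: `penumbra_sigma_iso` = 1.0 mm, `μ` = 0.0046/mm, `β` = 0.35/mm
(6 MV-FFF-like; buildup peak ≈ 14 mm).  These were fixed against a single
calibration anchor before any downstream number was inspected: the
two-central-leaf cones (2 leaf pairs, 1–3 mm gap) must put the
50%-of-maximum isodose volume in the virtual-cone literature range
0.051–0.093 cc; they land at 0.059/0.070/0.090 cc at the reduced preset.
Leaf transmission is zero (no interleaf leakage), apertures are centered
on the beam axis (the odd-leaf-pair half-leaf offset a real MLC would
need couch compensation for is ignored), and absolute output factors are
not modeled — every plan is renormalized to its target's D_99, so only
relative shape matters.

What the stand-in does *not* reproduce: phantom scatter (no low-dose
halo), spectral hardening, source occlusion at sub-penumbra field sizes,
and collimator-exchange effects.  One visible consequence: the composite
50% isodose of a 4 × 5 mm² static delivery has principal-axis extents of
6.3/5.2/7.6 mm — elongated along the vertical axis, which lies in all
three arc planes, and shortest along the couch axis, which is never a
beam direction.  A direct analytic summation (no interpolation)
reproduces these extents, so this is a property of the sharp,
scatter-free kernel, not of the delivery code; broad-penumbra Monte Carlo
kernels pull the same geometry toward a sphere.  Conclusions drawn from
passing tests therefore concern *relative* motion-induced degradation,
which is dominated by gradient scales the calibration anchor does pin
down, not absolute isodose shapes.

## Motion model

Six canonical traces displace the phantom equally on all three axes:
linear drifts reaching 0.5/1.0/1.5 mm per axis at the end of treatment
(3D offsets 0.87/1.73/2.60 mm) and sudden persistent 2-mm-per-axis steps
(3.46 mm 3D) at ¼, ½, ¾ of treatment.  Displacement is sampled at each
control point's `t` (piecewise-constant within a control point, matching
the discrete delivery model).  The dose pattern shifts by the *negative*
displacement — anatomy-fixed masks score the dose — and each control
point keeps its no-motion MU, scaled only by an inverse-square weight for
the proximal/distal shift of the beam entry point.  The default weight
derives the shift from the central ray's intersection with the displaced
sphere; a parallel-beam approximation `(SAD/(SAD+Δ∥))²` is kept for
cross-checks (they agree to <0.1% at these scales).  Drift direction is
+x, +y, +z; metrics on the spherical phantom are insensitive to the sign
choice.

## Metrics

D_x is the exact voxel-count quantile (largest dose covering at least x%
of the structure); DVH binning (0.5% of prescription) exists only for
plotting.  Structures are voxel-center-in-sphere masks: a centered target
of 1–10 mm diameter plus three 1-mm concentric shells.  V_x counts voxels
at or above x% of the prescription anywhere in the grid, with no
connected-component filtering (motion can split the prescription
isodose).  The no-motion plan is scaled so target D_99 = 100%; the motion
plan inherits the same scale.  Conformity degradation is the Paddick
ratio R_C = (TV_M²/PIV_M)/(TV_NO²/PIV_NO); falloff is GI = V_50/V_100;
plans with target D_max ≥ 200% are flagged infeasible but kept in
all-aperture averages (an option excludes them).  The dose-wash area
threshold is configurable (default 50% of prescription).  Note that a
literature worked example for R_C (TV ratio 0.732, PIV ratio 0.634) yields
0.845 by the formula even though the surrounding text calls it greater
than unity; the formula is authoritative here.

## Numerical choices and problem sizes

Kernels are sampled at 0.25-mm voxels in the `full` preset; routine
analyses and the replication grid use the `reduced` 0.5-mm preset and
fast unit checks a 1.0-mm `smoke` preset.  Plan dose is accumulated on a
±10-mm region of interest about isocenter — every target (≤10 mm), its
shells (≤8 mm radius), and the prescription-level isodose volumes sit
well inside; very low levels (V_10 for the largest apertures) may
truncate at the ROI boundary and are reported as such.  Grid convergence:
R_C at reduced vs full resolution agrees to 0.011 (tolerance 0.05) on the
tested cell.  The pipeline is fully deterministic — kernels, plans,
traces, and metrics contain no random stage — so reruns byte-reproduce
the metrics table; the run configuration still records a seed for
provenance.  Delivery cost is dominated by tricubic resampling
(~40 ms per control point on the reduced ROI); the multi-trace delivery
shares resamples between traces whose displacement coincides at a control
point (the no-motion trace and every pre-jump step trace, the post-jump
steps with each other), which roughly halves the replication grid.

## Known limitations

* Absolute dosimetry is out of reach by construction; only quantities
  that survive D_99 renormalization are meaningful.
* Off-axis targets are out of scope (the kernel is treated as spatially
  invariant, valid for the central target).
* No rotational patient motion, respiratory traces, or imaging/gating
  interventions; no dose-rate modulation or MLC motion within an arc.
* The composite isodose anisotropy described above means shape-sensitive
  absolute claims (e.g. 10% sphericity) should not be read off the
  synthetic kernels.
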