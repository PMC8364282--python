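import numpy as np
import pytest

from virtualcone.delivery import KernelSampler, rotation_matrix, superpose_plan
from virtualcone.geometry import ControlPoint, build_arc_plan
from virtualcone.kernels import sphere_mask
from virtualcone.metrics import dose_at_volume
from virtualcone.motion import (MotionTrace, deliver_traces,
                                deliver_with_motion, displacement_at,
                                inverse_square_weight, motion_hook,
                                standard_traces)


class TestDisplacement:
    def test_all_traces_start_at_zero(self):
        for trace in standard_traces().values():
            assert np.allclose(displacement_at(trace, 0.0), 0.0)

    def test_linear_drift_endpoint_offsets(self):
        """L_1.5 ends at 1.5 mm per axis, a 2.60-mm 3D offset; the drift
        family ends at 0.87/1.73/2.60 mm."""
        for amp, offset in [(0.5, 0.87), (1.0, 1.73), (1.5, 2.60)]:
            d = displacement_at(MotionTrace("linear_drift", amplitude=amp), 1.0)
            assert np.allclose(d, amp)
            assert np.linalg.norm(d) == pytest.approx(offset, abs=0.005)

    def test_sudden_step_jump(self):
        trace = standard_traces()["S_1/2"]
        assert np.allclose(displacement_at(trace, 0.49), 0.0)
        after = displacement_at(trace, 0.51)
        assert np.allclose(after, 2.0)
        assert np.linalg.norm(after) == pytest.approx(3.46, abs=0.005)

    def test_time_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            displacement_at(standard_traces()["L_1.0"], 1.2)
        with pytest.raises(ValueError):
            displacement_at(standard_traces()["L_1.0"], -0.1)

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            MotionTrace("wiggle")
        with pytest.raises(ValueError):
            MotionTrace("sudden_step", amplitude=2.0)  # missing fraction
        with pytest.raises(ValueError):
            MotionTrace("linear_drift", amplitude=-1.0)


class TestInverseSquareWeight:
    cp_down = ControlPoint(0.0, 0.0, 0.0, 0.5, 1.0)  # beam along −z

    def test_zero_displacement_is_unity(self, smoke_machine):
        for mode in ("parallel", "entry_point"):
            assert inverse_square_weight(self.cp_down, np.zeros(3),
                                         smoke_machine, mode) == 1.0

    def test_parallel_shift_toward_source(self, smoke_machine):
        # 10 mm toward the source (+z here) shortens the beamline: w > 1
        w = inverse_square_weight(self.cp_down, np.array([0, 0, 10.0]),
                                  smoke_machine, "parallel")
        assert w == pytest.approx((1000.0 / 990.0) ** 2, rel=1e-9)

    def test_parallel_perpendicular_displacement_is_unity(self, smoke_machine):
        w = inverse_square_weight(self.cp_down, np.array([3.0, -2.0, 0.0]),
                                  smoke_machine, "parallel")
        assert w == pytest.approx(1.0)

    def test_entry_point_agrees_with_parallel_at_small_shifts(self,
                                                              smoke_machine):
        """The ray–sphere entry-point correction and the parallel-beam
        approximation agree to <0.1% at millimetre displacement scales."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            cp = ControlPoint(rng.uniform(0, 360), rng.uniform(-45, 45),
                              rng.uniform(0, 180), 0.5, 1.0)
            d = rng.uniform(-2.0, 2.0, 3)
            wp = inverse_square_weight(cp, d, smoke_machine, "parallel")
            we = inverse_square_weight(cp, d, smoke_machine, "entry_point")
            assert we == pytest.approx(wp, rel=1e-3)

    def test_oversized_displacement_rejected(self, smoke_machine):
        with pytest.raises(ValueError):
            inverse_square_weight(self.cp_down, np.array([50.0, 0, 0]),
                                  smoke_machine)


class TestMotionDelivery:
    def test_none_trace_matches_plain_superposition(self, smoke_kernel,
                                                    smoke_aperture,
                                                    smoke_machine, smoke_roi):
        plan = build_arc_plan(smoke_aperture, "static", machine=smoke_machine)
        still = superpose_plan(smoke_kernel, plan, out_grid=smoke_roi)
        moved = deliver_with_motion(smoke_kernel, plan,
                                    standard_traces()["none"],
                                    smoke_machine, out_grid=smoke_roi)
        assert np.allclose(moved.values, still.values, rtol=1e-7, atol=1e-10)

    def test_sudden_step_two_segment_decomposition(self, smoke_kernel,
                                                   smoke_aperture,
                                                   smoke_machine, smoke_roi):
        """An S_1/4 delivery equals the unshifted dose from the first
        quarter of control points plus the constant-shift (ISQ-weighted)
        dose from the remaining three quarters."""
        plan = build_arc_plan(smoke_aperture, "static", machine=smoke_machine)
        trace = standard_traces()["S_1/4"]
        delivered = deliver_with_motion(smoke_kernel, plan, trace,
                                        smoke_machine, out_grid=smoke_roi)

        # independent accumulation, control point by control point
        sampler = KernelSampler(smoke_kernel)
        pts = smoke_roi.points()
        expected = np.zeros(pts.shape[1])
        shift = np.array([2.0, 2.0, 2.0])
        for cp in plan.control_points:
            rot = rotation_matrix(cp.gantry, cp.couch, cp.collimator)
            if cp.t < 0.25:
                expected += cp.weight * sampler.sample_points(
                    pts, rot, np.zeros(3))
            else:
                w = inverse_square_weight(cp, shift, smoke_machine)
                expected += cp.weight * w * sampler.sample_points(
                    pts, rot, -shift)
        n_early = sum(cp.t < 0.25 for cp in plan.control_points)
        assert n_early == plan.n_control_points // 4
        assert np.max(np.abs(delivered.values.ravel() - expected)) \
            <= 1e-6 * expected.max()

    def test_motion_hook_path_agrees_with_multi_trace_path(
            self, smoke_kernel, smoke_aperture, smoke_machine, smoke_roi):
        plan = build_arc_plan(smoke_aperture, "dynamic", machine=smoke_machine)
        trace = standard_traces()["L_1.0"]
        fast = deliver_with_motion(smoke_kernel, plan, trace, smoke_machine,
                                   out_grid=smoke_roi)
        hook = motion_hook(trace, smoke_machine)
        slow = superpose_plan(smoke_kernel, plan, out_grid=smoke_roi,
                              per_cp_transform_hook=hook)
        assert np.allclose(fast.values, slow.values, rtol=1e-7, atol=1e-10)

    def test_drift_reduces_target_coverage_dose(self, smoke_kernel,
                                                smoke_aperture, smoke_machine,
                                                smoke_roi):
        """L_1.5 strictly lowers D_95 of a centered 3-mm target."""
        plan = build_arc_plan(smoke_aperture, "static", machine=smoke_machine)
        tmask = sphere_mask(smoke_roi, 3.0)
        doses = deliver_traces(smoke_kernel, plan,
                               {"none": standard_traces()["none"],
                                "L_1.5": standard_traces()["L_1.5"]},
                               smoke_machine, out_grid=smoke_roi)
        d95_still = dose_at_volume(doses["none"], tmask, 95.0)
        d95_moved = dose_at_volume(doses["L_1.5"], tmask, 95.0)
        assert d95_moved < d95_still

    def test_mu_preservation_under_motion(self, smoke_kernel, smoke_aperture,
                                          smoke_machine):
        """The delivered integral dose under motion equals the no-motion
        integral modulated only by the inverse-square weights."""
        plan = build_arc_plan(smoke_aperture, "dynamic", machine=smoke_machine)
        doses = deliver_traces(smoke_kernel, plan,
                               {"none": standard_traces()["none"],
                                "L_1.0": standard_traces()["L_1.0"]},
                               smoke_machine)  # full kernel-sized grid
        ratio = doses["L_1.0"].values.sum() / doses["none"].values.sum()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_field_pushed_outside_grid_rejected(self, smoke_kernel,
                                                smoke_aperture, smoke_machine,
                                                smoke_roi):
        plan = build_arc_plan(smoke_aperture, "static", machine=smoke_machine)
        runaway = MotionTrace("linear_drift", amplitude=45.0)
        with pytest.raises(ValueError):
            deliver_with_motion(smoke_kernel, plan, runaway, smoke_machine,
                                out_grid=smoke_roi)
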