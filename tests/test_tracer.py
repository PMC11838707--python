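"""Tracer unit operations and end-to-end behaviour on phantoms."""

import numpy as np
import pytest

from seqseg import (
    AssemblyAccumulator,
    ImageVolume,
    OracleSegmenter,
    ProbabilityVolume,
    SubvolumeSpec,
    TracerConfig,
    TraceState,
    adaptive_subvolume,
    chance_step,
    is_retraced,
    next_sidelength,
    run_trace,
)
from seqseg.errors import ChancesExhausted, SeedOutsideImage


class TestNextSidelength:
    @pytest.mark.parametrize(
        "r_i,r_prev,expected",
        [(2.0, 3.0, 12.5), (2.0, 2.0, 10.0), (3.0, None, 15.0)],
    )
    def test_average_radius_rule(self, r_i, r_prev, expected):
        assert next_sidelength(r_i, r_prev) == expected

    def test_scaled_factor(self):
        assert next_sidelength(2.0, 2.0, factor=4.0) == 8.0


class TestAdaptiveSubvolume:
    def _image(self, n=64):
        return ImageVolume(np.zeros((n, n, n)), (1, 1, 1), (0, 0, 0))

    class _Uniform:
        def __init__(self, value):
            self.value = value
            self.calls = 0

        def predict(self, patch):
            self.calls += 1
            return ProbabilityVolume(
                np.full(patch.shape, self.value), patch.spacing, patch.origin
            )

    def test_small_fill_fraction_keeps_initial_cube(self):
        backend = self._Uniform(0.0)
        spec, prob, gamma, calls = adaptive_subvolume(
            self._image(), np.array([32.0, 32, 32]), 2.0, 2.0, backend, TracerConfig()
        )
        assert calls == 1
        assert spec.sidelength == 10.0
        assert gamma == 0.0

    def test_saturated_backend_compounds_then_breaks(self):
        backend = self._Uniform(1.0)
        spec, prob, gamma, calls = adaptive_subvolume(
            self._image(), np.array([32.0, 32, 32]), 2.0, 2.0, backend, TracerConfig()
        )
        # enlargements at 1.1, 1.21, 1.331 x L0, then the cap breaks the loop
        assert calls <= 4
        assert spec.sidelength / 10.0 <= 1.331 + 1e-9

    def test_gamma_counts_fraction_at_half(self):
        class Half:
            def predict(self, patch):
                data = np.zeros(patch.shape)
                data[: patch.shape[0] // 2] = 1.0
                return ProbabilityVolume(data, patch.spacing, patch.origin)

        _, _, gamma, _ = adaptive_subvolume(
            self._image(), np.array([32.0, 32, 32]), 2.0, 2.0, Half(),
            TracerConfig(gamma_star=0.9),
        )
        assert gamma == 0.5


class TestChanceStep:
    def _state(self, chances=0):
        return TraceState(
            point=np.zeros(3),
            tangent=np.array([1.0, 0, 0]),
            radius=2.0,
            radius_prev=2.0,
            previous_point=np.array([-2.0, 0, 0]),
            chances_used=chances,
        )

    def test_moves_one_radius_along_tangent(self):
        out = chance_step(self._state())
        assert np.allclose(out.point, [2, 0, 0])
        assert out.chances_used == 1
        assert np.allclose(out.tangent, [1, 0, 0])

    def test_fourth_attempt_exhausts(self):
        state = self._state()
        for _ in range(3):
            state = chance_step(state)
        assert state.chances_used == 3
        with pytest.raises(ChancesExhausted):
            chance_step(state)


class TestIsRetraced:
    def _setup(self):
        ref = ImageVolume(np.zeros((32, 32, 32)), (1, 1, 1), (0, 0, 0))
        acc = AssemblyAccumulator(ref)
        spec = SubvolumeSpec((15, 15, 15), 10.0, (21, 21, 21))
        data = np.zeros(spec.grid_shape)
        data[8:13, 8:13, 8:13] = 1.0
        pred = ProbabilityVolume(data, spec.patch_spacing, spec.low)
        return acc, spec, pred

    def test_empty_accumulator_is_not_retraced(self):
        acc, spec, pred = self._setup()
        assert not is_retraced(acc, spec, pred, [], TracerConfig())

    def test_fully_covered_region_is_retraced(self):
        acc, spec, pred = self._setup()
        acc.accumulate(pred, spec)
        assert is_retraced(acc, spec, pred, [], TracerConfig())

    def test_buffered_recent_steps_are_excluded(self):
        acc, spec, pred = self._setup()
        contrib = acc.contribution(pred, spec)
        sl, w, s = contrib
        acc.weighted_sum[sl] += w * s
        acc.weight_sum[sl] += w
        acc.contribution_count[sl] += 1
        assert not is_retraced(acc, spec, pred, [contrib], TracerConfig())


class TestRunTrace:
    def test_tube_trace_reaches_the_image_boundary(self, tube_trace):
        reasons = dict(tube_trace.termination_reasons)
        assert reasons[0] == "image_boundary"
        assert tube_trace.branches_traced == 1
        assert tube_trace.queue_entries_created == 0

    def test_work_bound_on_segmentation_calls(self, tube_trace):
        attempts = len(tube_trace.logs)
        assert tube_trace.total_steps <= TracerConfig().n_max
        assert tube_trace.segmentation_calls <= 4 * attempts

    def test_tube_centerline_progresses_monotonically(self, tube_trace):
        pts = tube_trace.centerline.branches[0].points
        assert np.all(np.diff(pts[:, 0]) > 0)

    def test_y_trace_queues_one_bifurcation_and_traces_it(self, y_trace):
        assert y_trace.queue_entries_created == 1
        assert y_trace.branches_traced == 2

    def test_single_step_budget(self, tube_phantom):
        image, label, _ = tube_phantom
        res = run_trace(
            image, ((10, 64, 64), (1, 0, 0), 4.0), OracleSegmenter(label),
            TracerConfig(n_max=1),
        )
        assert res.total_steps == 1
        assert ("max_steps" in [r for _, r in res.termination_reasons])

    def test_seed_outside_image_rejected(self, tube_phantom):
        image, _, _ = tube_phantom
        with pytest.raises(SeedOutsideImage):
            run_trace(image, ((-50, 0, 0), (1, 0, 0), 4.0), None, TracerConfig())

    def test_accepted_steps_accumulate_into_global_grids(self, tube_trace):
        acc = tube_trace.accumulator
        assert acc.contribution_count.max() >= 2  # overlapping cubes
        covered = acc.weight_sum > 0
        assert np.array_equal(covered, acc.contribution_count > 0)
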