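"""Cylinder correlation, correlation-line tracing, and orientation censuses."""

import numpy as np
import pytest

from planaquant import (
    CylinderTemplate,
    FiberSet,
    FiberTrace,
    RegionBox,
    VoxelGrid,
    classify_orientation,
    cylinder_correlate,
    fiber_region_stats,
    make_orientation_set,
    trace_correlation_lines,
)
from planaquant.fibers import _line_angles_deg, zncc_at
from planaquant.phantoms import DEFAULT_BODY_FRAME, _render_segment


def render_fiber(shape, center, axis, length, radius=2.8):
    img = np.zeros(shape, dtype=np.float32)
    c = np.asarray(center, dtype=float)
    u = np.asarray(axis, dtype=float)
    _render_segment(img, c - u * length / 2, c + u * length / 2, radius)
    return VoxelGrid(img)


class TestOrientationSet:
    def test_coarsest_set_contains_coordinate_axes(self):
        axes = make_orientation_set(90.0)
        for e in np.eye(3):
            assert _line_angles_deg(e[None], axes).min() < 1e-6

    @pytest.mark.parametrize("step", [30.0, 15.0, 10.0])
    def test_covering_property(self, step):
        """Any random axis lies within the angular step of a sample."""
        axes = make_orientation_set(step)
        rng = np.random.default_rng(7)
        probes = rng.normal(size=(1000, 3))
        probes /= np.linalg.norm(probes, axis=1, keepdims=True)
        worst = _line_angles_deg(probes, axes).min(axis=1).max()
        assert worst <= step

    def test_no_antipodal_pairs(self):
        axes = make_orientation_set(20.0)
        dots = axes @ axes.T
        np.fill_diagonal(dots, 0.0)
        assert dots.min() > -0.999999

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            make_orientation_set(0.0)
        with pytest.raises(ValueError):
            make_orientation_set(120.0)


class TestCylinderTemplate:
    def test_standard_recipe_parameters_accepted(self):
        tpl = CylinderTemplate(length=18, outer_radius=2.8, mask_radius=3, angular_step=5)
        assert tpl.length == 18

    def test_degenerate_template_rejected(self):
        with pytest.raises(ValueError):
            CylinderTemplate(length=4, outer_radius=2.8)
        with pytest.raises(ValueError):
            CylinderTemplate(mask_radius=1.0, outer_radius=2.8)


class TestCylinderCorrelate:
    def test_self_match_peak_and_orientation(self):
        """A noise-free cylinder matching the template, axis in the sample
        set: peak correlation >= 0.99 at the midpoint, orientation exact."""
        tpl = CylinderTemplate(angular_step=15)
        axes = make_orientation_set(15.0)
        u = axes[5]
        g = render_fiber((48, 48, 48), (24, 24, 24), u, length=18)
        field = cylinder_correlate(g, tpl)
        c = (24, 24, 24)
        assert field.correlation[c] >= 0.99
        err = _line_angles_deg(field.axis_at(c)[None], u[None])[0, 0]
        assert err <= 1e-6

    def test_arbitrary_axis_within_sampling_error(self):
        """For an axis between samples the recovered orientation is within
        the angular step."""
        step = 15.0
        tpl = CylinderTemplate(angular_step=step)
        rng = np.random.default_rng(3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        g = render_fiber((48, 48, 48), (24, 24, 24), u, length=18)
        field = cylinder_correlate(g, tpl)
        err = _line_angles_deg(field.axis_at((24, 24, 24))[None], u[None])[0, 0]
        assert err <= step

    def test_uniform_volume_zero_by_convention(self):
        g = VoxelGrid(np.full((40, 40, 40), 3.0, dtype=np.float32))
        field = cylinder_correlate(g, CylinderTemplate(angular_step=45))
        np.testing.assert_array_equal(field.correlation, 0.0)

    def test_agrees_with_direct_oracle_at_sampled_voxels(self):
        """FFT correlation equals explicit gather-and-dot evaluation within
        1e-4 at 20 random interior voxels."""
        tpl = CylinderTemplate(angular_step=30)
        axes = make_orientation_set(30.0)
        rng = np.random.default_rng(11)
        g = VoxelGrid(rng.random((44, 44, 44)).astype(np.float32))
        field = cylinder_correlate(g, tpl, axes=axes)
        half = int(np.ceil(tpl.length / 2 + tpl.mask_radius + 1))
        vox = rng.integers(half, 44 - half, size=(20, 3))
        for v in map(tuple, vox):
            direct = max(zncc_at(g, tpl, a, v) for a in axes)
            assert field.correlation[v] == pytest.approx(direct, abs=1e-4)

    def test_template_larger_than_grid_rejected(self):
        g = VoxelGrid(np.zeros((10, 10, 10), dtype=np.float32))
        with pytest.raises(ValueError):
            cylinder_correlate(g, CylinderTemplate(length=18))


class TestTraceCorrelationLines:
    def make_field(self, axis, length=100, shape=(64, 64, 128)):
        g = render_fiber(shape, np.asarray(shape) / 2, axis, length)
        return cylinder_correlate(g, CylinderTemplate(angular_step=15))

    def test_single_fiber_single_trace_with_length(self):
        field = self.make_field(np.array([0.0, 0.0, 1.0]))
        out = trace_correlation_lines(field, seed_threshold=0.5, min_length=20)
        assert len(out) == 1
        assert out.fibers[0].length == pytest.approx(100.0, rel=0.10)

    def test_two_parallel_fibers_two_traces(self):
        shape = (48, 64, 128)
        img = np.zeros(shape, dtype=np.float32)
        u = np.array([0.0, 0.0, 1.0])
        for y in (24, 40):  # separation 16 > 2 * mask_radius
            c = np.array([24.0, y, 64.0])
            _render_segment(img, c - u * 45, c + u * 45, 2.8)
        field = cylinder_correlate(VoxelGrid(img), CylinderTemplate(angular_step=15))
        out = trace_correlation_lines(field, seed_threshold=0.5, min_length=20)
        assert len(out) == 2

    def test_empty_field_no_traces(self):
        field = self.make_field(np.array([0.0, 0.0, 1.0]))
        out = trace_correlation_lines(field, seed_threshold=0.999999, min_length=20)
        assert len(out) == 0

    def test_threshold_validation(self):
        field = self.make_field(np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            trace_correlation_lines(field, seed_threshold=2.0)
        with pytest.raises(ValueError):
            trace_correlation_lines(field, seed_threshold=0.5, continue_threshold=0.9)


def make_trace(direction, trace_id=0, length=50.0, offset=(0, 0, 0)):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    t = np.linspace(0, length, 11)
    pts = np.asarray(offset, dtype=float) + t[:, None] * d
    return FiberTrace(pts, d, trace_id=trace_id)


class TestClassifyOrientation:
    frame = DEFAULT_BODY_FRAME  # AP = x, ML = y, DV = z

    def classify_one(self, direction):
        fs = FiberSet([make_trace(direction)])
        classify_orientation(fs, self.frame)
        return fs.fibers[0].fiber_class

    def test_canonical_directions(self):
        assert self.classify_one([0, 0, 1]) == "longitudinal"  # along AP
        assert self.classify_one([0, 1, 1]) == "diagonal"  # 45 deg in plane
        assert self.classify_one([0, 1, 0]) == "circular"  # along ML
        assert self.classify_one([1, 0, 0]) == "dorsoventral"  # along DV

    def test_ap_sign_flip_invariance(self):
        flipped = np.array([[0, 0, -1.0], [0, 1, 0], [1, 0, 0]])
        for d in ([0, 0, 1], [0, 1, 1], [0, 1, 0], [1, 0, 0], [0.3, 0.5, 0.9]):
            fs1 = FiberSet([make_trace(d)])
            fs2 = FiberSet([make_trace(d)])
            classify_orientation(fs1, self.frame)
            classify_orientation(fs2, flipped)
            assert fs1.fibers[0].fiber_class == fs2.fibers[0].fiber_class

    def test_non_orthonormal_frame_rejected(self):
        bad = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError):
            classify_orientation(FiberSet([make_trace([0, 0, 1])]), bad)


class TestFiberRegionStats:
    def test_counts_and_proportions(self):
        fibers = [make_trace([0, 1, 0], i, offset=(10, 10, 10)) for i in range(10)]
        fibers += [make_trace([0, 0, 1], 10 + i, offset=(10, 10, 10)) for i in range(5)]
        fs = FiberSet(fibers)
        classify_orientation(fs, DEFAULT_BODY_FRAME)
        box = RegionBox((0, 0, 0), (100, 100, 100), name="census")
        stats = fiber_region_stats(fs, box)
        by_class = stats.set_index("class")
        assert by_class.loc["circular", "count"] == 10
        assert by_class.loc["longitudinal", "count"] == 5
        assert by_class.loc["circular", "proportion"] == pytest.approx(2 / 3)
        assert stats["proportion"].dropna().sum() == pytest.approx(1.0)

    def test_empty_region_null_proportions(self):
        fs = FiberSet([make_trace([0, 1, 0], 0, offset=(200, 200, 200))])
        box = RegionBox((0, 0, 0), (100, 100, 100))
        stats = fiber_region_stats(fs, box)
        assert stats["count"].sum() == 0
        assert stats["proportion"].isna().all()

    def test_census_box_expressible(self):
        box = RegionBox((0, 0, 0), (300, 250, 500), name="pole")
        assert box.upper == (300.0, 250.0, 500.0)


class TestFiberSetExport:
    def test_dataframe_and_spatial_graph(self, tmp_path):
        fs = FiberSet([make_trace([0, 0, 1], 1), make_trace([0, 1, 0], 2)])
        classify_orientation(fs, DEFAULT_BODY_FRAME)
        df = fs.to_dataframe()
        assert list(df["id"]) == [1, 2]
        assert set(df.columns) >= {"length_um", "class", "mid_x_um"}
        graph = fs.to_spatial_graph()
        assert len(graph["nodes"]) == 22
        assert len(graph["edges"]) == 20
        out = tmp_path / "fibers.json"
        fs.save_spatial_graph(out)
        import json

        back = json.loads(out.read_text())
        assert len(back["nodes"]) == 22
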