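"""Surface extraction, cap detection, role assignment, centerlines."""

import numpy as np
import pytest
from scipy import ndimage

from seqseg import (
    LabelVolume,
    OracleSegmenter,
    PhantomConfig,
    ProbabilityVolume,
    SubvolumeSpec,
    assign_roles,
    clip_and_caps,
    compute_centerline,
    extract_subvolume,
    generate_tree,
    segment,
    stepping_points,
    surface_from_probability,
    voxelize,
)
from seqseg.centerline import Branch, CenterlineTree
from seqseg.eikonal import eikonal_solve
from seqseg.errors import CenterlineFailure, InsufficientOutlets, NoSurface

from oracles import dijkstra_times


def _ball_patch(r_vox=8, pad=4):
    n = 2 * (r_vox + pad) + 1
    c = r_vox + pad
    g = np.indices((n, n, n))
    d2 = sum((g[a] - c) ** 2 for a in range(3))
    data = (d2 <= r_vox**2).astype(float)
    return ProbabilityVolume(data, (1, 1, 1), (0, 0, 0))


def _cylinder(radius=5.0, length=40, ny=21):
    mask = np.zeros((length, ny, ny), np.uint8)
    yy, zz = np.meshgrid(np.arange(ny), np.arange(ny), indexing="ij")
    c = (ny - 1) / 2
    mask[:, ((yy - c) ** 2 + (zz - c) ** 2) <= radius**2] = 1
    return LabelVolume(mask, (1, 1, 1), (0, 0, 0)), c


class TestSurface:
    def test_ball_surface_area_near_analytic(self):
        mesh = surface_from_probability(_ball_patch(8))
        assert abs(mesh.area - 4 * np.pi * 64) / (4 * np.pi * 64) < 0.10

    def test_empty_level_set_raises(self):
        prob = ProbabilityVolume(np.zeros((8, 8, 8)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(NoSurface):
            surface_from_probability(prob)

    def test_interior_blob_mesh_is_watertight(self):
        mesh = surface_from_probability(_ball_patch(6))
        edges, counts = np.unique(mesh.edges_sorted, axis=0, return_counts=True)
        assert np.all(counts == 2)


class TestClipAndCaps:
    @pytest.fixture(scope="class")
    def tube_patch(self):
        tree = generate_tree("tube", start=(0, 24, 24), direction=(1, 0, 0),
                             length=70, radius=4, rng=0)
        img, lab, _ = voxelize(tree, PhantomConfig(grid_shape=(72, 48, 48), noise_sd=0),
                               allow_exit=True)
        spec = SubvolumeSpec((35, 24, 24), 20.0, (48, 48, 48))
        prob = segment(OracleSegmenter(lab), extract_subvolume(img, spec))
        return spec, prob

    def test_straight_tube_yields_two_caps_on_opposite_faces(self, tube_patch):
        spec, prob = tube_patch
        mesh = surface_from_probability(prob)
        _, caps = clip_and_caps(mesh, spec)
        assert len(caps) == 2
        faces = sorted(c.face for c in caps)
        assert faces == [0, 1]  # -x and +x inset planes
        for cap in caps:
            assert abs(cap.center[0] - spec.center[0]) > 8  # near a face
            assert np.allclose(cap.center[1:], [24, 24], atol=1.0)
            assert cap.radius == pytest.approx(4.0, rel=0.2)

    def test_y_junction_patch_yields_three_caps(self):
        tree = generate_tree("y_bifurcation", start=(6, 40, 40), direction=(1, 0, 0),
                             length=30, radius=4, child_ratio=0.7, length_ratio=0.9,
                             branch_angle_deg=(35, 40), rng=1)
        img, lab, _ = voxelize(tree, PhantomConfig(grid_shape=(96, 80, 80), noise_sd=0))
        junction = tree.branches[0].polyline[-1]
        spec = SubvolumeSpec(tuple(junction + [1.0, 0, 0]), 22.0, (48, 48, 48))
        prob = segment(OracleSegmenter(lab), extract_subvolume(img, spec))
        _, caps = clip_and_caps(surface_from_probability(prob), spec)
        assert len(caps) == 3

    def test_closed_blob_yields_no_caps(self):
        prob = _ball_patch(6)
        spec = SubvolumeSpec((12.0, 12.0, 12.0), 24.0, prob.shape)
        clipped, caps = clip_and_caps(surface_from_probability(prob), spec)
        assert caps == []


class TestAssignRoles:
    def _cap(self, center):
        from seqseg.geometry import CapBoundary

        loop = np.asarray(center) + np.array([[0, 1, 0], [0, 0, 1], [0, -1, 0], [0, 0, -1.0]])
        return CapBoundary.from_loop(loop, 0)

    def test_nearest_cap_becomes_source(self):
        caps = [self._cap((0, 0, 0)), self._cap((20, 0, 0))]
        out = assign_roles(caps, (1, 0, 0))
        assert out[0].role == "source"
        assert out[1].role == "target"

    def test_three_caps_one_source_two_targets(self):
        caps = [self._cap((0, 0, 0)), self._cap((20, 0, 0)), self._cap((10, 10, 0))]
        out = assign_roles(caps, (19, 0, 0))
        roles = [c.role for c in out]
        assert roles.count("source") == 1
        assert roles.count("target") == 2
        assert out[1].role == "source"

    def test_single_cap_is_insufficient(self):
        with pytest.raises(InsufficientOutlets):
            assign_roles([self._cap((0, 0, 0))], (0, 0, 0))


class TestCenterline:
    def test_cylinder_axis_recovered_within_one_voxel(self):
        vol, c = _cylinder(radius=5.0)
        tree = compute_centerline(vol, np.array([0.0, c, c]), [np.array([39.0, c, c])])
        b = tree.branches[0]
        deviation = np.linalg.norm(b.points[:, 1:] - c, axis=1)
        assert deviation.max() <= 1.0

    def test_cylinder_radius_estimate_within_ten_percent(self):
        vol, c = _cylinder(radius=5.0)
        tree = compute_centerline(vol, np.array([0.0, c, c]), [np.array([39.0, c, c])])
        b = tree.branches[0]
        s = b.arclengths
        mid = (s > 0.3 * s[-1]) & (s < 0.7 * s[-1])
        assert np.all(np.abs(b.radii[mid] - 5.0) / 5.0 <= 0.10)

    def test_radius_bounded_by_inscribed_sphere(self):
        vol, c = _cylinder(radius=5.0)
        dist = ndimage.distance_transform_edt(vol.data, sampling=vol.spacing)
        tree = compute_centerline(vol, np.array([0.0, c, c]), [np.array([39.0, c, c])])
        b = tree.branches[0]
        # maximal inscribed sphere radius anywhere in this cylinder
        assert np.all(b.radii <= dist.max() + 1.0)

    def test_disconnected_target_fails(self):
        mask = np.zeros((30, 9, 9), np.uint8)
        mask[:10, 3:6, 3:6] = 1
        mask[20:, 3:6, 3:6] = 1  # gap in the middle
        vol = LabelVolume(mask, (1, 1, 1), (0, 0, 0))
        with pytest.raises(CenterlineFailure):
            compute_centerline(vol, np.array([0.0, 4, 4]), [np.array([29.0, 4, 4])])

    def test_recomputation_is_bitwise_deterministic(self):
        vol, c = _cylinder(radius=4.0, length=25)
        a = compute_centerline(vol, np.array([0.0, c, c]), [np.array([24.0, c, c])])
        b = compute_centerline(vol, np.array([0.0, c, c]), [np.array([24.0, c, c])])
        assert np.array_equal(a.branches[0].points, b.branches[0].points)
        assert np.array_equal(a.branches[0].radii, b.branches[0].radii)


class TestSteppingPoints:
    def test_point_at_eighty_percent_arclength(self):
        pts = np.stack([np.linspace(0, 10, 21), np.zeros(21), np.zeros(21)], axis=1)
        tree = CenterlineTree(branches=[Branch(pts, np.full(21, 1.0))],
                              source=pts[0], targets=[pts[-1]])
        out = stepping_points(tree, fraction=0.8)
        assert len(out) == 1
        point, tangent, radius = out[0]
        assert np.allclose(point, [8, 0, 0], atol=1e-9)
        assert np.allclose(tangent, [1, 0, 0])

    def test_tangents_are_unit_vectors(self, rng):
        t = np.linspace(0, 2 * np.pi, 60)
        pts = np.stack([10 * np.cos(t), 10 * np.sin(t), t], axis=1)
        tree = CenterlineTree(branches=[Branch(pts, np.full(60, 1.0))],
                              source=pts[0], targets=[pts[-1]])
        for _, tangent, _ in stepping_points(tree):
            assert abs(np.linalg.norm(tangent) - 1) < 1e-9

    def test_two_target_tree_gives_two_points(self):
        trunk = np.stack([np.linspace(0, 10, 11), np.zeros(11), np.zeros(11)], axis=1)
        arm = np.stack([np.linspace(5, 10, 6), np.linspace(0, 5, 6), np.zeros(6)], axis=1)
        tree = CenterlineTree(
            branches=[Branch(trunk, np.full(11, 1.0)), Branch(arm, np.full(6, 1.0), parent=0)],
            source=trunk[0],
            targets=[trunk[-1], arm[-1]],
        )
        assert len(stepping_points(tree)) == 2


class TestEikonal:
    def test_arrival_times_match_dijkstra_along_path(self):
        # bent tube in an 18^3 grid; compare away from the source voxel,
        # where a relative criterion on two first-order discretizations
        # is meaningful
        mask = np.zeros((18, 18, 18), bool)
        mask[2:16, 7:12, 7:12] = True
        mask[12:16, 7:12, 7:16] = True
        spacing = np.array([1.0, 1.0, 1.0])
        dist = ndimage.distance_transform_edt(mask, sampling=spacing)
        speed = np.maximum(dist, 0.1)
        src = np.array([2, 9, 9])
        T = eikonal_solve(speed, mask, src, spacing)
        TD = dijkstra_times(speed, mask, src, spacing)

        vol = LabelVolume(mask.astype(np.uint8), spacing, (0, 0, 0))
        tree = compute_centerline(vol, np.array([2.0, 9, 9]), [np.array([14.0, 9, 15.0])])
        idx = np.unique(np.round(tree.branches[0].points).astype(int), axis=0)
        idx = idx[mask[tuple(idx.T)]]
        t_fm = T[tuple(idx.T)]
        t_dj = TD[tuple(idx.T)]
        far = t_dj >= 0.25 * t_dj.max()
        rel = np.abs(t_fm[far] - t_dj[far]) / t_dj[far]
        assert rel.max() <= 0.15

    def test_front_is_monotone_from_source(self):
        mask = np.ones((10, 10, 10), bool)
        speed = np.ones((10, 10, 10))
        T = eikonal_solve(speed, mask, np.array([0, 0, 0]), (1, 1, 1))
        assert T[0, 0, 0] == 0.0
        # along an axis, T equals the distance for unit speed
        assert np.allclose(T[:, 0, 0], np.arange(10), atol=1e-5)
        assert np.all(np.isfinite(T))
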