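import networkx as nx
import numpy as np
import pytest

from mtmesh.fit import (
    CenterlineGraph,
    DegeneratePolylineError,
    EmptyForegroundError,
    FitError,
    FitParams,
    binarize,
    fit_cylinder,
    fit_network,
    place_linkers,
    skeletonize,
    trace_segments,
)
from mtmesh.synth import make_fixture_network, render_network
from mtmesh.volume import VoxelVolume


def _binary(data, spacing=(0.12, 0.12, 0.12)):
    return VoxelVolume(data=data.astype(np.uint8), spacing=spacing, bit_depth=8)


def _graph_from_points(points_um, spacing=(0.12, 0.12, 0.12)):
    """CenterlineGraph from a chain of physical points (test scaffolding)."""
    g = nx.Graph()
    nodes = []
    for k, p in enumerate(points_um):
        node = (k, 0, 0)
        g.add_node(node, coord=np.asarray(p, dtype=float))
        nodes.append(node)
    for a, b in zip(nodes, nodes[1:]):
        g.add_edge(a, b)
    return CenterlineGraph(graph=g, spacing=spacing)


class TestBinarize:
    def test_constant_volume_all_background(self):
        vol = VoxelVolume(data=np.full((4, 4, 4), 7, dtype=np.uint8), spacing=(0.1,) * 3, bit_depth=8)
        out = binarize(vol, threshold=10)
        assert not out.data.any()

    def test_rendered_cylinder_single_component(self, noiseless_cylinder_render):
        vol = noiseless_cylinder_render[0]
        out = binarize(vol, threshold=float(vol.data.max()) / 2)
        from skimage.measure import label

        _, n = label(out.data.astype(bool), connectivity=3, return_num=True)
        assert n == 2  # the fixture holds two disjoint filaments

    def test_speckles_removed(self):
        rng = np.random.default_rng(0)
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        ones = rng.integers(0, 20, (30, 3))
        data[tuple(ones.T)] = 255
        out = binarize(_binary(data), threshold=100, min_component_voxels=27)
        assert not out.data.any()

    def test_non_finite_threshold_rejected(self):
        vol = _binary(np.zeros((4, 4, 4)))
        with pytest.raises(FitError):
            binarize(vol, threshold=float("nan"))


class TestSkeletonize:
    def test_cylinder_skeleton_length_within_15_percent(self, noiseless_cylinder_render):
        vol = noiseless_cylinder_render[0]
        b = binarize(vol, threshold=float(vol.data.max()) / 2)
        graph = skeletonize(b)
        total = sum(
            np.linalg.norm(graph.coord(a) - graph.coord(b_)) for a, b_ in graph.graph.edges
        )
        # two 4-um filaments; thinning erodes about one apparent radius per cap
        assert abs(total - 8.0) / 8.0 < 0.15

    def test_sphere_collapses_to_at_most_a_few_voxels(self):
        from conftest import antialiased_sphere

        vol = antialiased_sphere(radius_um=0.6, pitch_um=0.12)
        b = binarize(vol, threshold=500)
        graph = skeletonize(b)
        assert graph.graph.number_of_nodes() <= 5

    def test_crossing_cylinders_have_a_branch_point(self):
        model = make_fixture_network("crossing")
        vol, _ = render_network(model, snr=np.inf, seed=0)
        b = binarize(vol, threshold=float(vol.data.max()) / 2)
        graph = skeletonize(b)
        assert len(graph.branch_points) >= 1

    def test_empty_foreground_rejected(self):
        with pytest.raises(EmptyForegroundError):
            skeletonize(_binary(np.zeros((4, 4, 4))))

    def test_edges_within_voxel_diagonal(self, noiseless_cylinder_render):
        vol = noiseless_cylinder_render[0]
        b = binarize(vol, threshold=float(vol.data.max()) / 2)
        skeletonize(b).validate()


class TestTraceSegments:
    def test_straight_path_is_one_polyline(self):
        pts = [(0.1 * k, 0.0, 0.0) for k in range(40)]
        polylines, rejected = trace_segments(_graph_from_points(pts))
        assert len(polylines) == 1
        assert rejected == 0

    def test_right_angle_corner_splits_in_two(self):
        run = [(0.1 * k, 0.0, 0.0) for k in range(20)]
        run += [(1.9, 0.1 * k, 0.0) for k in range(1, 20)]
        polylines, _ = trace_segments(_graph_from_points(run))
        assert len(polylines) == 2

    def test_gentle_curve_stays_whole(self):
        # total turn 10 degrees over 4 um: below the 20 degree local limit
        s = np.linspace(0, 4.0, 50)
        theta = np.radians(10) * s / 4.0
        pts = np.stack([np.cumsum(np.gradient(s) * np.cos(theta)),
                        np.cumsum(np.gradient(s) * np.sin(theta)),
                        np.zeros_like(s)], axis=1)
        polylines, _ = trace_segments(_graph_from_points(pts))
        assert len(polylines) == 1

    def test_short_fragments_counted_as_rejected(self):
        pts = [(0.1 * k, 0.0, 0.0) for k in range(6)]  # 0.5 um < 1 um minimum
        polylines, rejected = trace_segments(_graph_from_points(pts))
        assert polylines == []
        assert rejected == 1


class TestFitCylinder:
    def test_collinear_points_recover_length(self):
        pts = np.array([(0.12 * k, 0.0, 0.0) for k in range(34)])  # ~4 um
        vol = _binary(np.zeros((4, 4, 40)))
        fil, residual = fit_cylinder(pts, vol, assigned_voxels=np.empty((0, 3)))
        assert fil.length == pytest.approx(0.12 * 33, abs=0.12)
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_two_point_polyline_rejected(self):
        vol = _binary(np.zeros((4, 4, 4)))
        with pytest.raises(DegeneratePolylineError):
            fit_cylinder(np.array([[0, 0, 0], [1.0, 0, 0]]), vol)

    def test_zero_extent_polyline_rejected(self):
        vol = _binary(np.zeros((4, 4, 4)))
        with pytest.raises(DegeneratePolylineError):
            fit_cylinder(np.zeros((5, 3)), vol)

    def test_rendered_cylinder_recovery(self):
        from mtmesh.model import Filament, FilamentNetworkModel

        model = FilamentNetworkModel(
            filaments=[Filament("F0", np.array([0.0, 0, 0]), np.array([4.0, 0, 0]), 0.25)],
            units="um",
        )
        vol, _ = render_network(model, snr=np.inf, seed=0)
        fitted, _ = fit_network(vol)
        assert len(fitted.filaments) == 1
        f = fitted.filaments[0]
        assert abs(f.length - 4.0) / 4.0 < 0.10
        angle = np.degrees(np.arccos(np.clip(abs(f.axis @ [1.0, 0, 0]), 0, 1)))
        assert angle < 5.0
        assert f.radius > 0.25  # PSF inflation
        assert not f.polarity_verified


class TestFitNetwork:
    def test_two_parallel_closure(self, two_parallel_render):
        model, report = fit_network(two_parallel_render[0])
        assert len(model.filaments) == 2
        assert len(model.joints) == 0
        assert report.coverage > 0.8

    def test_empty_volume_raises(self):
        vol = VoxelVolume(data=np.zeros((8, 8, 8), dtype=np.uint16), spacing=(0.12,) * 3)
        with pytest.raises((EmptyForegroundError, FitError)):
            fit_network(vol, FitParams(threshold=10))

    def test_aster3_closure(self):
        model = make_fixture_network("aster3")
        vol, _ = render_network(model, snr=10, seed=4)
        fitted, report = fit_network(vol)
        assert abs(len(fitted.filaments) - 6) <= 1
        assert len(fitted.joints) >= 1

    def test_deterministic(self, two_parallel_render):
        m1, r1 = fit_network(two_parallel_render[0])
        m2, r2 = fit_network(two_parallel_render[0])
        assert len(m1.filaments) == len(m2.filaments)
        for a, b in zip(m1.filaments, m2.filaments):
            np.testing.assert_array_equal(a.end_minus, b.end_minus)
        assert r1.coverage == r2.coverage

    def test_coverage_non_decreasing_as_min_length_drops(self, two_parallel_render):
        _, strict = fit_network(two_parallel_render[0], FitParams(min_length_um=2.0))
        _, loose = fit_network(two_parallel_render[0], FitParams(min_length_um=1.0))
        assert loose.coverage >= strict.coverage - 1e-12

    def test_fitted_radius_shrinks_with_psf(self, two_parallel_model):
        radii = []
        for sigma in ((0.2, 0.5), (0.1, 0.25), (0.05, 0.12)):
            vol, _ = render_network(two_parallel_model, psf_sigma=sigma, snr=np.inf, seed=0)
            fitted, _ = fit_network(vol)
            radii.append(np.mean([f.radius for f in fitted.filaments]))
        assert radii[0] > radii[1] > radii[2]
        assert all(r > 0.25 for r in radii)  # inflated above the true radius


class TestPlaceLinkers:
    def test_motility_element_regains_its_linker(self):
        model = make_fixture_network("motility_element")
        vol_f, vol_l = render_network(model, snr=10, seed=2)
        fitted, _ = fit_network(vol_f)
        with_linkers = place_linkers(fitted, vol_l)
        assert len(with_linkers.linkers) == 1
        lk = with_linkers.linkers[0]
        assert {h.filament_id for h in lk.heads} == {f.id for f in fitted.filaments}

    def test_no_blobs_no_linkers(self, two_parallel_render):
        fitted, _ = fit_network(two_parallel_render[0])
        out = place_linkers(fitted, two_parallel_render[1])
        assert len(out.linkers) == 0
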