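"""Centerline extraction, junction detection, and confluence demarcation."""

import numpy as np
import pytest

from confluencemorph.centerline import (
    DegenerateConfluenceError,
    JunctionNode,
    TopologyError,
    arc_length,
    demarcate_confluence,
    extract_centerline_tree,
    find_junctions,
    trace_skeleton_path,
)
from confluencemorph.io import LabelSchema, LabelVolume, Role
from confluencemorph.phantom import PhantomConfig, make_phantom


class TestArcLength:
    def test_three_four_five(self):
        assert arc_length([(0, 0, 0), (3, 4, 0)]) == pytest.approx(5.0)

    def test_closed_unit_square(self):
        square = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 0)]
        assert arc_length(square) == pytest.approx(4.0)

    def test_semicircle_converges_to_pi(self):
        t = np.linspace(0.0, np.pi, 1000)
        poly = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        assert arc_length(poly) == pytest.approx(np.pi, abs=1e-4)

    def test_at_least_chord_length(self, rng):
        poly = rng.normal(size=(20, 3))
        assert arc_length(poly) >= np.linalg.norm(poly[-1] - poly[0]) - 1e-12

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            arc_length([(0, 0, 0)])


class TestTracing:
    def test_one_voxel_line_is_its_own_centerline(self):
        mask = np.zeros((20, 3, 3), dtype=bool)
        mask[2:17, 1, 1] = True
        poly = trace_skeleton_path(mask, spacing=(0.5, 0.5, 0.5), smooth=False, extend=False)
        expected = np.stack(
            [np.arange(2, 17) * 0.5, np.full(15, 0.5), np.full(15, 0.5)], axis=1
        )
        if poly[0, 0] > poly[-1, 0]:
            poly = poly[::-1]
        assert np.allclose(poly, expected)

    def test_straight_cylinder_axis_recovery(self):
        # radius 4 mm, length 40 mm along x at 0.5 mm spacing
        sp = 0.5
        shape = (96, 24, 24)
        idx = np.indices(shape).astype(float)
        x = idx[0] * sp
        y = idx[1] * sp - 6.0
        z = idx[2] * sp - 6.0
        mask = (np.hypot(y, z) <= 4.0) & (x >= 4.0) & (x <= 44.0)
        poly = trace_skeleton_path(mask, spacing=(sp, sp, sp))
        # every point within one voxel of the true axis (y=z=0 in this frame)
        dev = np.hypot(poly[:, 1] - 6.0, poly[:, 2] - 6.0)
        assert dev.max() <= sp
        assert arc_length(poly) == pytest.approx(40.0, rel=0.05)

    def test_l_shaped_tube_length(self):
        sp = 0.5
        shape = (70, 70, 20)
        idx = np.indices(shape).astype(float) * sp
        x, y, z = idx[0], idx[1] - 5.0, idx[2] - 5.0
        limb1 = (np.hypot(y, z) <= 3.0) & (x >= 5.0) & (x <= 25.0)
        limb2 = (np.hypot(x - 25.0, z) <= 3.0) & (y >= 0.0) & (y <= 20.0)
        poly = trace_skeleton_path(limb1 | limb2, spacing=(sp, sp, sp))
        assert arc_length(poly) == pytest.approx(40.0, rel=0.075)

    def test_refinement_improves_axis_accuracy(self):
        devs = {}
        for sp in (1.0, 0.5):
            n = int(30 / sp)
            m = int(12 / sp)
            idx = np.indices((n, m, m)).astype(float) * sp
            y, z = idx[1] - 6.0, idx[2] - 6.0
            mask = np.hypot(y + 0.2, z - 0.3) <= 3.5
            poly = trace_skeleton_path(mask, spacing=(sp, sp, sp))
            devs[sp] = np.hypot(poly[:, 1] - (6.0 - 0.2), poly[:, 2] - (6.0 + 0.3)).max()
        assert devs[0.5] <= devs[1.0]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            trace_skeleton_path(np.zeros((4, 4, 4), dtype=bool), spacing=(1, 1, 1))


class TestTreeExtraction:
    def test_branch_per_structure(self, slab_phantom):
        vol, _ = slab_phantom
        tree = extract_centerline_tree(vol)
        for role in (Role.PVC, Role.LUPV, Role.RUPV, Role.LIPV, Role.RIPV, Role.VV):
            assert role in tree.branches
            assert tree.branches[role].shape[0] >= 2

    def test_consecutive_spacing_bounded(self, slab_phantom):
        vol, _ = slab_phantom
        tree = extract_centerline_tree(vol)
        for poly in tree.branches.values():
            steps = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            assert steps.max() <= 2.0 * tree.voxel_diagonal

    def test_main_channel_near_true_axis(self, slab_phantom):
        vol, truth = slab_phantom
        tree = extract_centerline_tree(vol)
        main = tree.branches[Role.PVC]
        # axis is x=0, z=3 over the confluence span
        dev = np.hypot(main[:, 0], main[:, 2] - 3.0)
        assert dev.max() <= np.linalg.norm(vol.spacing)

    def test_empty_venous_label_named(self, slab_phantom):
        vol, _ = slab_phantom
        vox = vol.voxels.copy()
        vox[vox == vol.schema[Role.VV]] = 0
        bad = LabelVolume(vox, vol.spacing, vol.origin, vol.schema)
        with pytest.raises(TopologyError, match="VV"):
            extract_centerline_tree(bad, require_complete=True)

    def test_disconnected_label_reports_sizes(self, slab_phantom):
        vol, _ = slab_phantom
        vox = vol.voxels.copy()
        vox[0, 0, 0] = vol.schema[Role.PVC]    # stray fragment far from the tube
        bad = LabelVolume(vox, vol.spacing, vol.origin, vol.schema)
        with pytest.raises(TopologyError, match="disconnected"):
            extract_centerline_tree(bad)

    def test_whole_voxel_translation_equivariance(self):
        cfg = PhantomConfig(
            confluence_length=20.0, slab_extent=(30.0, 5.0, 10.0), pv_length=8.0
        )
        vol, _ = make_phantom(cfg)
        shift_vox = (3, 2, 1)
        shift_mm = np.array(shift_vox) * np.array(vol.spacing)
        moved = LabelVolume(
            vol.voxels.copy(),
            vol.spacing,
            tuple(np.array(vol.origin) + shift_mm),
            vol.schema,
        )
        t0 = extract_centerline_tree(vol)
        t1 = extract_centerline_tree(moved)
        for role in t0.branches:
            assert np.allclose(t1.branches[role], t0.branches[role] + shift_mm)


def _seg_dist(pts, a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ab = b - a
    t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)


def _three_tube_volume():
    """Main channel along x with two stubs meeting it at one point."""
    sp = 0.5
    shape = (60, 44, 44)
    idx = np.indices(shape).reshape(3, -1).T.astype(float) * sp
    junction = np.array([20.0, 11.0, 11.0])
    main = _seg_dist(idx, [2.0, 11.0, 11.0], junction) <= 2.0
    stub_a = _seg_dist(idx, junction, junction + [6.0, 7.0, 0.0]) <= 2.0
    stub_b = _seg_dist(idx, junction, junction + [6.0, -7.0, 0.0]) <= 2.0
    schema = LabelSchema()
    vox = np.zeros(shape[0] * shape[1] * shape[2], dtype=np.uint8)
    vox[main] = schema[Role.PVC]
    vox[stub_a & (vox == 0)] = schema[Role.RUPV]
    vox[stub_b & (vox == 0)] = schema[Role.RIPV]
    return LabelVolume(vox.reshape(shape), (sp, sp, sp), (0, 0, 0), schema)


class TestJunctions:
    def test_slab_junctions_near_truth(self, slab_phantom):
        vol, truth = slab_phantom
        tree = extract_centerline_tree(vol)
        nodes = find_junctions(tree, vol, required=True)
        vox_diag = np.linalg.norm(vol.spacing)
        right = next(n for n in nodes if {Role.RUPV, Role.RIPV} <= n.roles)
        left = next(n for n in nodes if {Role.LUPV, Role.VV} <= n.roles)
        assert np.linalg.norm(right.position - truth.junction_right) <= vox_diag
        assert np.linalg.norm(left.position - truth.junction_left) <= vox_diag

    def test_three_tubes_one_node_three_roles(self):
        vol = _three_tube_volume()
        tree = extract_centerline_tree(vol)
        nodes = find_junctions(tree, vol)
        assert len(nodes) == 1
        assert nodes[0].roles == {Role.PVC, Role.RUPV, Role.RIPV}

    def test_unbranched_tube_has_no_junctions(self):
        sp = 0.5
        idx = np.indices((60, 20, 20)).astype(float) * sp
        mask = (np.hypot(idx[1] - 5.0, idx[2] - 5.0) <= 2.0) & (idx[0] >= 2) & (idx[0] <= 28)
        vox = np.where(mask, LabelSchema()[Role.PVC], 0).astype(np.uint8)
        vol = LabelVolume(vox, (sp, sp, sp))
        tree = extract_centerline_tree(vol)
        assert find_junctions(tree, vol) == []

    def test_detached_vein_is_topology_error(self, slab_phantom):
        vol, _ = slab_phantom
        vox = vol.voxels.copy()
        # move the RUPV label far away from the confluence
        src = vox == vol.schema[Role.RUPV]
        vox[src] = 0
        vox[2:5, 2:5, 2:5] = vol.schema[Role.RUPV]
        bad = LabelVolume(vox, vol.spacing, vol.origin, vol.schema)
        tree = extract_centerline_tree(bad)
        with pytest.raises(TopologyError, match="RUPV"):
            find_junctions(tree, bad)


class TestDemarcation:
    def test_slab_segment_matches_truth(self, slab_phantom):
        vol, truth = slab_phantom
        tree = extract_centerline_tree(vol)
        seg = demarcate_confluence(tree, find_junctions(tree, vol, required=True))
        assert seg.length_mm == pytest.approx(30.0, rel=0.05)
        vox_diag = np.linalg.norm(vol.spacing)
        assert np.linalg.norm(seg.polyline[0] - truth.junction_right) <= 2 * vox_diag
        assert np.linalg.norm(seg.polyline[-1] - truth.junction_left) <= 2 * vox_diag

    def test_sphere_arc_segment_length(self, sphere_phantom):
        vol, _ = sphere_phantom
        tree = extract_centerline_tree(vol)
        seg = demarcate_confluence(tree, find_junctions(tree, vol, required=True))
        # centerline arc (R+g)*theta = 22, not the projected CCL
        assert seg.length_mm == pytest.approx(22.0, rel=0.05)

    def test_segment_stays_inside_main_channel_support(self, slab_phantom):
        vol, _ = slab_phantom
        tree = extract_centerline_tree(vol)
        seg = demarcate_confluence(tree, find_junctions(tree, vol, required=True))
        idx = np.argwhere(vol.mask(Role.PVC))
        support = np.asarray(vol.origin) + idx * np.asarray(vol.spacing)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(support).query(seg.polyline)
        assert d.max() <= np.linalg.norm(vol.spacing)

    def test_coincident_junctions_degenerate(self, slab_phantom):
        vol, _ = slab_phantom
        tree = extract_centerline_tree(vol)
        node = JunctionNode(
            position=np.array([0.0, 15.0, 3.0]),
            roles=frozenset({Role.PVC, Role.RUPV, Role.RIPV, Role.LUPV, Role.VV}),
        )
        with pytest.raises(DegenerateConfluenceError):
            demarcate_confluence(tree, [node, node])

    def test_type_ib_mirrored_demarcation(self):
        vol, truth = make_phantom(PhantomConfig(vv_side="right"))
        tree = extract_centerline_tree(vol)
        seg = demarcate_confluence(tree, find_junctions(tree, vol, required=True))
        assert seg.length_mm == pytest.approx(30.0, rel=0.05)
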