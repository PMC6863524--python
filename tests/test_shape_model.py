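"""Voxel volumes: STL voxelization, resampling, labeling generators, fixtures."""

import math

import numpy as np
import pytest
import trimesh

from scafslicer import (
    LabeledVolume,
    label_by_thickness,
    label_linear_gradient,
    label_shells,
    make_fixture,
    resample,
    voxelize_mesh,
)
from scafslicer.shape_model import local_thickness


class TestVoxelize:
    def test_axis_aligned_cube_counts(self):
        mesh = trimesh.creation.box(extents=(10, 10, 10))
        vol = voxelize_mesh(mesh, 0.5)
        assert vol.shape == (20, 20, 20)
        assert int(vol.occupied.sum()) == 8000
        # independent oracle: every voxel center must be inside the box
        for axis in range(3):
            c = vol.centers(axis)
            assert ((c > vol.origin[axis]) & (c < vol.origin[axis] + 10)).all()

    def test_sphere_volume_fraction(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=5)
        vol = voxelize_mesh(mesh, 0.1)
        frac = vol.occupied.mean()
        assert frac == pytest.approx(math.pi / 6, rel=0.01)

    def test_shape_dropped_one_layer_above_bed(self):
        mesh = trimesh.creation.box(extents=(4, 4, 4))
        vol = voxelize_mesh(mesh, 0.5)
        assert vol.origin[2] == pytest.approx(0.5)

    def test_open_mesh_rejected_with_edge_count(self):
        box = trimesh.creation.box(extents=(5, 5, 5))
        open_mesh = trimesh.Trimesh(vertices=box.vertices, faces=box.faces[:-1])
        with pytest.raises(ValueError, match=r"not watertight: \d+ open"):
            voxelize_mesh(open_mesh, 0.5)

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError):
            voxelize_mesh(trimesh.Trimesh(), 0.5)

    def test_marching_round_trip_volume(self):
        """Voxelize -> exact surface -> volume stays within 2% at R/25 pitch."""
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=5)
        vol = voxelize_mesh(mesh, 0.2)
        voxel_volume = vol.occupied.sum() * vol.pitch**3
        assert voxel_volume == pytest.approx(mesh.volume, rel=0.02)


class TestResample:
    def test_identity(self):
        vol = make_fixture("box", (2, 2, 2), 0.5)
        same = resample(vol, 0.5)
        assert np.array_equal(same.labels, vol.labels)

    def test_exact_sixfold_upsample(self):
        vol = make_fixture("box", (1.8, 1.8, 1.8), 0.6)
        up = resample(vol, 0.1)
        assert up.shape == (18, 18, 18)
        assert int(up.occupied.sum()) == 216 * int(vol.occupied.sum())
        assert np.allclose(up.upper, vol.upper)

    def test_downsample_preserves_extent(self):
        vol = make_fixture("box", (4, 4, 2), 0.1)
        down = resample(vol, 0.4)
        assert np.allclose(down.upper, vol.upper)
        assert down.occupied.all()


class TestLinearGradient:
    def test_equal_slabs_on_commensurate_cube(self):
        vol = make_fixture("box", (30, 30, 30), 0.5)
        lab = label_linear_gradient(vol, "x", 5)
        counts = [int((lab.labels == i).sum()) for i in range(1, 6)]
        assert counts == [60 * 60 * 12] * 5
        # slab order follows the axis
        assert lab.labels[0, 0, 0] == 1 and lab.labels[-1, 0, 0] == 5

    def test_single_region(self):
        vol = make_fixture("box", (5, 5, 5), 0.5)
        lab = label_linear_gradient(vol, "z", 1)
        assert set(np.unique(lab.labels[lab.occupied])) == {1}

    def test_too_many_regions_rejected(self):
        vol = make_fixture("box", (2, 2, 2), 0.5)
        with pytest.raises(ValueError):
            label_linear_gradient(vol, "x", 100)


class TestShells:
    def test_nested_cube_shell_volumes_exact(self):
        """Depth binning of a cube gives the analytic nested-box volumes."""
        vol = make_fixture("box", (30, 30, 30), 0.5)
        sh = label_shells(vol, [5.0, 10.0])
        counts = [int((sh.labels == i).sum()) for i in (1, 2, 3)]
        assert counts == [60**3 - 40**3, 40**3 - 20**3, 20**3]

    def test_sphere_half_radius_shell(self):
        vol = make_fixture("sphere", (10.0,), 0.25)
        sh = label_shells(vol, [5.0])
        outer_fraction = (sh.labels == 1).sum() / sh.occupied.sum()
        assert outer_fraction == pytest.approx(7 / 8, abs=0.01)

    def test_boundary_beyond_inradius_gives_single_label(self):
        vol = make_fixture("box", (4, 4, 4), 0.5)
        sh = label_shells(vol, [100.0])
        assert set(np.unique(sh.labels[sh.occupied])) == {1}

    def test_shell_index_monotone_with_depth(self):
        vol = make_fixture("sphere", (6.0,), 0.25)
        sh = label_shells(vol, [1.0, 2.0, 3.0])
        # along a ray from the surface to the center labels never decrease
        n = sh.shape[0]
        ray = sh.labels[: n // 2, n // 2, n // 2]
        ray = ray[ray > 0]
        assert (np.diff(ray) >= 0).all()


class TestThickness:
    def test_uniform_plate_thickness_within_pitch(self):
        vol = make_fixture("box", (20, 20, 2), 0.25)
        thick = local_thickness(vol)
        interior = thick[20:60, 20:60, :]
        assert np.all(np.abs(interior - 2.0) <= 0.25 + 1e-9)

    def test_two_joined_plates_split_by_threshold(self):
        labels = np.zeros((80, 40, 12), dtype=np.int16)
        labels[:40, :, :4] = 1  # 1 mm plate
        labels[40:, :, :] = 1  # 3 mm plate
        vol = LabeledVolume(labels, 0.25)
        lab = label_by_thickness(vol, [2.0])
        assert set(np.unique(lab.labels[5:30, 5:35, :4])) == {1}
        assert set(np.unique(lab.labels[50:75, 5:35, :])) == {2}

    def test_empty_threshold_list_single_label(self):
        vol = make_fixture("box", (4, 4, 4), 0.5)
        lab = label_by_thickness(vol, [])
        assert set(np.unique(lab.labels[lab.occupied])) == {1}


@pytest.mark.parametrize(
    "op",
    [
        lambda v: label_linear_gradient(v, "x", 3),
        lambda v: label_shells(v, [1.0, 2.0]),
        lambda v: label_by_thickness(v, [3.0]),
    ],
)
def test_labeling_preserves_occupied_voxels(op):
    """Labeling relabels the occupied set exactly; never adds or removes."""
    vol = make_fixture("blob", (12, 12, 8), 0.4, seed=7)
    out = op(vol)
    assert np.array_equal(out.occupied, vol.occupied)


class TestFixtures:
    def test_box_counts(self):
        vol = make_fixture("box", (20, 20, 10), 0.1)
        assert vol.shape == (200, 200, 100)
        assert vol.occupied.all()

    def test_floating_box_sits_at_gap(self):
        vol = make_fixture("floating_box", (10, 10, 5), 0.5, gap=2.0)
        assert vol.origin[2] == pytest.approx(2.0)

    def test_cylinder_cross_section(self):
        vol = make_fixture("cylinder", (5.0, 4.0), 0.1)
        frac = vol.occupied[:, :, 0].mean()
        assert frac == pytest.approx(math.pi / 4, rel=0.01)

    def test_blob_deterministic_under_seed(self):
        a = make_fixture("blob", (10, 10, 10), 0.5, seed=3)
        b = make_fixture("blob", (10, 10, 10), 0.5, seed=3)
        c = make_fixture("blob", (10, 10, 10), 0.5, seed=4)
        assert np.array_equal(a.labels, b.labels)
        assert not np.array_equal(a.labels, c.labels)
        assert a.occupied.any()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("torus", (1, 2), 0.5)


def test_volume_save_load_round_trip(tmp_path):
    vol = make_fixture("blob", (8, 8, 6), 0.5, seed=1)
    vol.save(tmp_path / "vol")
    back = LabeledVolume.load(tmp_path / "vol")
    assert np.array_equal(back.labels, vol.labels)
    assert back.pitch == vol.pitch
    assert np.allclose(back.origin, vol.origin)
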