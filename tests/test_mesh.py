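"""Voxel masks, structured slabs and the biventricular phantom."""

import numpy as np
import pytest

from hexaheart.mesh import (HexMesh, TAG_ENDO_LV, TAG_ENDO_RV, TAG_EPI,
                            VoxelMask, assign_nine_regions,
                            build_biventricular_phantom, build_slab_mesh,
                            build_stair_stepped_mesh, mesh_edge_stats)


def test_slab_counts_and_coordinates():
    mesh = build_slab_mesh((400.0, 200.0, 100.0), 100.0)
    assert mesh.n_nodes == 5 * 3 * 2
    assert mesh.n_elements == 4 * 2 * 1
    assert mesh.nodes.min() == 0.0
    assert mesh.nodes[:, 0].max() == 400.0


def test_slab_graded_edges():
    # 425+184+191 = 800 um cycles exactly twice into 1600 um
    mesh = build_slab_mesh((1600.0, 200.0, 200.0),
                           {"x": [425.0, 184.0, 191.0], "y": 200.0,
                            "z": 200.0})
    xs = np.unique(mesh.nodes[:, 0])
    assert np.allclose(np.diff(xs), [425, 184, 191, 425, 184, 191])


def test_slab_rejects_bad_extent():
    with pytest.raises(ValueError):
        build_slab_mesh((0.0, 100.0, 100.0), 100.0)
    with pytest.raises(ValueError):
        build_slab_mesh((100.0, 100.0, 100.0), -5.0)


def test_stair_stepped_mesh_matches_mask():
    occ = np.zeros((3, 3, 3), dtype=bool)
    occ[1, 1, 1] = True
    occ[1, 1, 2] = True
    mask = VoxelMask(occ, 100.0)
    mesh = build_stair_stepped_mesh(mask, 100.0)
    assert mesh.n_elements == 2
    assert mesh.n_nodes == 12  # two stacked voxels share a face


def test_hexmesh_validation():
    nodes = np.zeros((4, 3))
    with pytest.raises(ValueError):
        HexMesh(nodes, np.arange(8)[None, :])  # node ids out of range
    with pytest.raises(ValueError):
        HexMesh(np.full((8, 3), np.nan), np.arange(8)[None, :])


def test_phantom_two_cavities_and_tags(small_phantom):
    mask, mesh = small_phantom
    tags = mesh.surface_tags
    for tag in (TAG_ENDO_LV, TAG_ENDO_RV, TAG_EPI):
        assert (tags == tag).sum() > 0, tag
    lv = mesh.nodes[tags == TAG_ENDO_LV]
    rv = mesh.nodes[tags == TAG_ENDO_RV]
    # cavities on opposite sides of the septum
    assert lv[:, 0].max() < 0 < rv[:, 0].min()
    assert mask.n_occupied == mesh.n_elements


def test_phantom_is_watertight_shell(small_phantom):
    _, mesh = small_phantom
    stats = mesh_edge_stats(mesh)
    assert stats.min_edge == stats.max_edge == 400.0
    # every element has 8 distinct nodes
    assert all(len(set(e)) == 8 for e in mesh.elements)


def test_nine_regions_cover_myocardium(small_phantom):
    _, mesh = small_phantom
    labels = set(mesh.region_labels)
    assert "" not in labels
    assert len(labels) == 9
    for tz in ("endo", "M", "epi"):
        for lz in ("apex", "center", "base"):
            assert f"{tz}/{lz}" in labels


def test_nine_regions_are_ordered(small_phantom):
    _, mesh = small_phantom
    cent = mesh.element_centroids()
    z_of = {lz: cent[np.char.endswith(mesh.region_labels, lz), 2].mean()
            for lz in ("apex", "center", "base")}
    assert z_of["apex"] < z_of["center"] < z_of["base"]


def test_phantom_rejects_degenerate_parameters():
    with pytest.raises(ValueError):
        build_biventricular_phantom(wall_thickness=100.0, edge=400.0)
    with pytest.raises(ValueError):
        build_biventricular_phantom(outer_radii=(1000.0, 1000.0, 1000.0),
                                    wall_thickness=1200.0, edge=100.0)
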