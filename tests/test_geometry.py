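"""Labyrinth generator: labeling invariants, mirror, orientation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvstim.geometry import (
    CANALS,
    PATCHES,
    HeadOrientation,
    LabyrinthConfig,
    build_labyrinth,
    cupula_connected,
    cupula_separates,
    mirror_labyrinth,
    orient,
)


def test_all_patches_and_regions_present(left_geom):
    assert left_geom.present_patches() == set(PATCHES)
    for canal in CANALS:
        assert len(left_geom.region_cells(f"cupula_{canal}")) > 0


@pytest.mark.parametrize("canal", CANALS)
def test_cupula_is_connected_and_seals(left_geom, canal):
    assert cupula_connected(left_geom, canal)
    assert cupula_separates(left_geom, canal)


def test_build_is_deterministic(mini_config):
    g1 = build_labyrinth(mini_config)
    g2 = build_labyrinth(mini_config)
    assert np.array_equal(g1.mesh.vertices, g2.mesh.vertices)
    assert np.array_equal(g1.mesh.cells, g2.mesh.cells)
    assert np.array_equal(g1.face_patch, g2.face_patch)


def test_resolution_doubling_keeps_topology(mini_config):
    import dataclasses

    coarse = build_labyrinth(mini_config)
    fine = build_labyrinth(dataclasses.replace(mini_config, voxel_mm=mini_config.voxel_mm / 2))
    assert coarse.present_patches() == fine.present_patches()
    for canal in CANALS:
        assert len(fine.region_cells(f"cupula_{canal}")) > 0
    assert fine.mesh.n_cells >= 4 * coarse.mesh.n_cells


def test_infeasible_geometry_rejected():
    with pytest.raises(ValueError, match="torus radius > duct radius"):
        LabyrinthConfig(duct_radius_mm=3.2, canal_major_radius_mm=3.2).validate()
    with pytest.raises(ValueError, match="resolution too coarse"):
        build_labyrinth(LabyrinthConfig(min_cells=10**9))


# -- mirror -------------------------------------------------------------------

def test_mirror_reflects_through_sagittal_plane(left_geom):
    right = mirror_labyrinth(left_geom)
    assert right.side == "right"
    assert np.abs(right.mesh.vertices[:, 1] + left_geom.mesh.vertices[:, 1]).max() < 1e-9
    assert np.array_equal(right.mesh.vertices[:, [0, 2]], left_geom.mesh.vertices[:, [0, 2]])
    assert np.array_equal(right.face_patch, left_geom.face_patch)
    assert np.array_equal(right.cell_region, left_geom.cell_region)


def test_mirror_rejects_right_input(left_geom):
    right = mirror_labyrinth(left_geom)
    with pytest.raises(ValueError, match="left"):
        mirror_labyrinth(right)


def test_mirror_is_isometry(left_geom):
    right = mirror_labyrinth(left_geom)
    assert np.isclose(right.mesh.total_volume(), left_geom.mesh.total_volume(), rtol=1e-12)
    rng = np.random.default_rng(0)
    idx = rng.integers(0, left_geom.mesh.n_vertices, size=(200, 2))
    dl = np.linalg.norm(
        left_geom.mesh.vertices[idx[:, 0]] - left_geom.mesh.vertices[idx[:, 1]], axis=1
    )
    dr = np.linalg.norm(
        right.mesh.vertices[idx[:, 0]] - right.mesh.vertices[idx[:, 1]], axis=1
    )
    assert np.allclose(dl, dr, rtol=1e-12, atol=1e-12)


def test_mirror_flips_utriculopetal_y_component(left_geom):
    right = mirror_labyrinth(left_geom)
    for canal in CANALS:
        a, b, c = left_geom.crista_frames[canal]["utriculopetal"]
        am, bm, cm = right.crista_frames[canal]["utriculopetal"]
        assert np.allclose([am, bm, cm], [a, -b, c], atol=1e-12)


# -- head orientation ----------------------------------------------------------

def test_supine_b_vector_conventions(left_geom):
    head = HeadOrientation()
    _, B = orient(left_geom, head, 7.0, "head_to_feet")
    assert np.allclose(B, [0, 0, -7.0])
    _, B2 = orient(left_geom, head, 7.0, "feet_to_head")
    assert np.allclose(B2, -B)


def test_rotation_trace_identity(left_geom):
    head = HeadOrientation(ets_deg=40.0, pitch_offset_deg=0.0)
    R = head.rotation
    assert np.isclose(np.trace(R), 1 + 2 * np.cos(np.radians(40.0)), atol=1e-12)


def test_orientation_angle_range_enforced():
    with pytest.raises(ValueError, match="ets_deg"):
        HeadOrientation(ets_deg=-180.0)
    HeadOrientation(ets_deg=180.0)  # boundary included


@settings(max_examples=25, deadline=None)
@given(
    ets=st.floats(-179.9, 180.0),
    fe=st.floats(-179.9, 180.0),
)
def test_rotation_is_proper_orthonormal(ets, fe):
    R = HeadOrientation(ets_deg=ets, fe_deg=fe).rotation
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
    assert np.isclose(np.linalg.det(R), 1.0, atol=1e-12)


def test_orient_preserves_volume_and_patch_areas(left_geom):
    head = HeadOrientation(ets_deg=-40.0, fe_deg=25.0)
    rotated, _ = orient(left_geom, head, 3.0, "head_to_feet")
    assert np.isclose(
        rotated.mesh.total_volume(), left_geom.mesh.total_volume(), rtol=1e-12
    )
    for p in ("hair_macula", "dark_utricle", "hair_crista_H"):
        assert np.isclose(rotated.patch_area(p), left_geom.patch_area(p), rtol=1e-12)


def test_point_location_roundtrip(left_geom):
    head = HeadOrientation(ets_deg=20.0)
    rotated, _ = orient(left_geom, head, 7.0, "head_to_feet")
    cents = rotated.mesh.centroids()[::4000]
    cid = rotated.locate_points(cents)
    assert (cid >= 0).all()
    outside = rotated.locate_points(np.array([[50.0, 50.0, 50.0]]))
    assert outside[0] == -1
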