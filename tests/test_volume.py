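"""Nerve rasterization, threshold segmentation and centerline round-trips."""

import numpy as np
import pytest

from phrenicmap import (HUVolume, Polyline3, extract_centerline,
                        points_to_polyline_distances, rasterize_nerve,
                        roundtrip_distance_error, segment_hu_threshold)
from phrenicmap.volume import VoxelSet


def _blank(shape=(60, 21, 21), spacing=1.0, origin=(-10.0, -10.0, -10.0)):
    return HUVolume(np.zeros(shape, np.float32), (spacing,) * 3, origin)


STRAIGHT = Polyline3([[0, 0, 0], [40, 0, 0]])


def test_rasterize_marks_exactly_within_radius():
    """A voxel is marked iff its center is within width*spacing/2 of the line."""
    vol = _blank()
    out = rasterize_nerve(STRAIGHT, vol, width_voxels=5, hu_value=900)
    idx = np.indices(vol.shape).reshape(3, -1).T
    centers = vol.voxel_centers(idx)
    d = points_to_polyline_distances(centers, STRAIGHT)
    marked = out.data[idx[:, 0], idx[:, 1], idx[:, 2]] == 900
    assert np.array_equal(marked, d <= 2.5)


def test_rasterize_count_matches_analytic_capsule():
    """Marked-voxel count ~ capsule volume (cylinder + end caps) within 10%."""
    vol = _blank()
    out = rasterize_nerve(STRAIGHT, vol)
    n = int((out.data == 900).sum())
    r, length = 2.5, 40.0
    capsule = np.pi * r ** 2 * length + 4 / 3 * np.pi * r ** 3
    assert abs(n - capsule) / capsule < 0.10


def test_rasterize_preserves_background_and_is_idempotent():
    vol = _blank()
    vol.data[:] = 40.0
    vol.data[0, 0, 0] = -1000.0  # far corner, outside the tube
    once = rasterize_nerve(STRAIGHT, vol)
    assert once.data[0, 0, 0] == -1000.0
    assert once.data[55, 18, 18] == 40.0
    twice = rasterize_nerve(STRAIGHT, once)
    assert np.array_equal(once.data, twice.data)


def test_rasterize_out_of_bounds_names_vertex():
    vol = _blank(shape=(20, 20, 20))
    path = Polyline3([[0, 0, 0], [500, 0, 0]])
    with pytest.raises(ValueError, match="vertex 1"):
        rasterize_nerve(path, vol)


def test_segment_threshold_behaviour():
    vol = _blank()
    assert len(segment_hu_threshold(vol)) == 0
    vol.data[:] = 40.0  # soft-tissue background well below the marker
    out = rasterize_nerve(STRAIGHT, vol)
    seg = segment_hu_threshold(out, hu_min=850)
    expect = np.argwhere(out.data == 900)
    assert sorted(map(tuple, seg.indices)) == sorted(map(tuple, expect))
    assert len(segment_hu_threshold(out, hu_min=901)) == 0


def test_voxelset_bounds_checked():
    with pytest.raises(ValueError, match="bounds"):
        VoxelSet([[5, 5, 99]], (1, 1, 1), (0, 0, 0), (10, 10, 10))


def test_centerline_single_voxel_degenerate():
    vx = VoxelSet([[3, 4, 5]], (1, 1, 1), (0, 0, 0), (10, 10, 10))
    line = extract_centerline(vx)
    assert line.is_degenerate
    assert np.allclose(line.vertices[0], [3, 4, 5])


def test_centerline_disconnected_reports_components():
    vx = VoxelSet([[0, 0, 0], [1, 0, 0], [8, 8, 8], [9, 8, 8]],
                  (1, 1, 1), (0, 0, 0), (10, 10, 10))
    with pytest.raises(ValueError, match="2 components"):
        extract_centerline(vx)


def test_centerline_straight_tube_collinear():
    """Straight rasterized tube: centerline within half a voxel diagonal of truth."""
    vol = _blank()
    out = rasterize_nerve(STRAIGHT, vol)
    line = extract_centerline(segment_hu_threshold(out), smooth_window_mm=5.0)
    dev = points_to_polyline_distances(line.vertices, STRAIGHT)
    assert dev.max() <= np.sqrt(3) / 2
    # endpoints near the true endpoints
    assert np.linalg.norm(line.vertices[0] - [0, 0, 0]) <= np.sqrt(3) or \
        np.linalg.norm(line.vertices[0] - [40, 0, 0]) <= np.sqrt(3)


def _hausdorff(a: Polyline3, b: Polyline3, step=0.2):
    pa, pb = a.sample(step), b.sample(step)
    return max(points_to_polyline_distances(pa, b).max(),
               points_to_polyline_distances(pb, a).max())


def test_centerline_curved_roundtrip():
    """Curved tube (curvature radius >= 20 mm): Hausdorff <= one voxel diagonal."""
    s = np.linspace(0, np.pi / 1.5, 60)
    path = Polyline3(np.c_[25 * np.cos(s), 25 * np.sin(s), 4 * s])
    pad = 6.0
    lo = path.vertices.min(axis=0) - pad
    shape = tuple(np.ceil((path.vertices.max(axis=0) + pad - lo)).astype(int) + 1)
    vol = HUVolume(np.zeros(shape, np.float32), (1.0,) * 3, lo)
    out = rasterize_nerve(path, vol)
    line = extract_centerline(segment_hu_threshold(out), smooth_window_mm=5.0)
    assert _hausdorff(line, path) <= np.sqrt(3)


def test_roundtrip_error_bounds(rng):
    site_far = np.array([[20.0, 30.0, 0.0]])  # ~30 mm off the path
    err = roundtrip_distance_error(STRAIGHT, 1.0, site_far)
    assert err[0] <= 1.8  # one 1 mm voxel diagonal
    err_fine = roundtrip_distance_error(STRAIGHT, 0.25, site_far)
    assert err_fine[0] <= 0.5
    assert roundtrip_distance_error(STRAIGHT, 1.0, np.empty((0, 3))).size == 0


def test_nifti_roundtrip(tmp_path):
    vol = _blank(shape=(8, 9, 10), spacing=0.5, origin=(1.0, 2.0, 3.0))
    vol.data[2, 3, 4] = 900.0
    f = tmp_path / "vol.nii.gz"
    vol.save_nifti(f)
    back = HUVolume.load_nifti(f)
    assert np.array_equal(back.data, vol.data)
    assert np.allclose(back.spacing, vol.spacing)
    assert np.allclose(back.origin, vol.origin)
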