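"""En-face reslicing, LoG spot detection and per-plane counting."""

import numpy as np
import pytest

import axonquant as aq
from axonquant.detect import ResliceGeometry, SpotSet, count_profile, detect_spots_plane
from axonquant.errors import GeometryError, ParameterError
from axonquant.io import DetectorParams
from axonquant.render import make_grid_for_scene
from conftest import straight_scene
from oracles import bruteforce_spots


def _blob_plane(centers, shape=(64, 64), sigma=1.5, amp=100.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    plane = np.zeros(shape)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for r0, c0 in centers:
        plane += amp * np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)))
    if noise:
        plane += rng.normal(0, noise, size=shape)
    return plane


def test_coincident_axis_points_rejected():
    with pytest.raises(GeometryError, match="coincide"):
        ResliceGeometry.from_points((0, 0, 0), (0, 0, 0))


def test_constant_stack_reslices_to_constant_planes():
    stack = aq.CalibratedStack(np.full((10, 20, 30), 5.0), (2.45, 1.24, 1.24))
    geom = ResliceGeometry.from_points((11.0, 11.0, 0.0), (11.0, 11.0, 30.0), halfwidth_um=8.0)
    planes = aq.reslice_en_face(stack, geom, np.arange(5.0, 25.0))
    assert np.allclose(planes, 5.0)


def test_tube_center_stable_across_planes():
    """A single axial tube reslices to one blob whose centre stays on the
    centreline (within the 1 µm sampling) across planes."""
    scene = straight_scene(n_y=1, n_z=1, nerve_radius_um=25.0,
                           conduit_inner_radius_um=30.0, conduit_wall_um=5.0)
    stack = aq.render_stack(scene, fov_halfwidth_um=(40.0, 40.0))
    grid = make_grid_for_scene(scene, fov_halfwidth_um=(40.0, 40.0))
    p0, p1 = grid.axis_annotation()
    geom = ResliceGeometry.from_points(p0, p1, halfwidth_um=20.0)
    planes = aq.reslice_en_face(stack, geom, np.arange(20.0, 300.0, 20.0))
    centers = [np.unravel_index(np.argmax(p), p.shape) for p in planes]
    centers = np.asarray(centers, dtype=float)
    assert np.all(np.abs(centers - centers[0]) <= 1.0)


def test_blank_plane_yields_no_spots():
    spots = detect_spots_plane(np.zeros((40, 40)))
    assert spots.count == 0


def test_three_blobs_recovered_within_one_micron():
    truth = [(12.0, 14.0), (30.0, 40.0), (50.0, 20.0)]
    plane = _blob_plane(truth, noise=1.0)
    spots = detect_spots_plane(plane, DetectorParams())
    assert spots.count == 3
    for t in truth:
        dist = np.min(np.linalg.norm(spots.centers_um - np.array(t), axis=1))
        assert dist <= 1.0


def test_detector_matches_bruteforce_on_random_planes(rng):
    params = DetectorParams()
    for _ in range(10):
        shape = tuple(rng.integers(16, 65, size=2))
        n_blobs = int(rng.integers(0, 5))
        centers = rng.uniform(4, min(shape) - 4, size=(n_blobs, 2))
        plane = _blob_plane(centers, shape=shape, noise=2.0, seed=int(rng.integers(2**31)))
        spots = detect_spots_plane(plane, params)
        ref_centers, ref_resp = bruteforce_spots(plane, params)
        assert spots.count == len(ref_centers)
        assert np.array_equal(spots.centers_um, ref_centers)
        assert np.allclose(spots.responses, ref_resp)


def test_counting_invariant_under_global_scaling():
    plane = _blob_plane([(20.0, 20.0), (40.0, 45.0)], noise=2.0)
    base = detect_spots_plane(plane).count
    for k in (1e-3, 1e3):
        assert detect_spots_plane(plane * k).count == base


def test_nonfinite_plane_rejected():
    plane = np.zeros((20, 20))
    plane[3, 3] = np.nan
    with pytest.raises(ParameterError, match="finite"):
        detect_spots_plane(plane)


def test_sigma_below_sampling_rejected():
    with pytest.raises(ParameterError, match="sigma"):
        detect_spots_plane(np.zeros((10, 10)), DetectorParams(sigma_um=0.5))


def test_count_profile_marks_unacquired_positions_missing():
    sets = [SpotSet(0.0, np.zeros((2, 2)), np.ones(2)), SpotSet(2.0, np.empty((0, 2)), np.empty(0))]
    positions, counts = count_profile(sets, np.array([0.0, 1.0, 2.0]))
    assert counts[0] == 2 and np.isnan(counts[1]) and counts[2] == 0


def test_count_profile_rejects_duplicates():
    sets = [SpotSet(1.0, np.empty((0, 2)), np.empty(0))] * 2
    with pytest.raises(ParameterError, match="duplicate"):
        count_profile(sets)


def test_empty_spotsets_give_all_zero_profile():
    sets = [SpotSet(float(p), np.empty((0, 2)), np.empty(0)) for p in range(5)]
    _, counts = count_profile(sets)
    assert np.all(counts == 0)


def test_noiseless_default_scene_detection_close_to_truth():
    """Full render → reslice → detect chain on a default-parameter scene with
    noise and conduit texture off: the summed count error over the analysis
    window stays within 2% of the true total."""
    p = aq.SceneParams(seed=0, autofluorescence_level=0.0, read_noise_sd=0.0, photon_scale=0.0)
    scene = aq.generate_scene(p)
    stack = aq.render_stack(scene)
    grid = make_grid_for_scene(scene)
    p0, p1 = grid.axis_annotation()
    geom = ResliceGeometry.from_points(p0, p1, halfwidth_um=50.0)
    rel = np.arange(-1000, 2001)
    positions = rel + grid.lesion_stack_x_um(scene)
    spotsets = aq.detect_profile(stack, geom, positions.astype(float))
    detected = np.array([s.count for s in spotsets])
    truth = aq.true_profile(scene, rel).true_counts
    assert np.abs(detected - truth).sum() <= 0.02 * truth.sum()
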