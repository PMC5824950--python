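"""Background subtraction, strided ROI scan, bead-mode detection."""

import numpy as np
import pytest
from scipy import ndimage

from budsort.detection import (RoiSpec, detect_particle, scan_for_cell,
                               subtract_background)
from budsort.synth import (BACKGROUND_INTENSITY, make_cell, render_frame)

ROI = RoiSpec(x_offset_px=10, y_offset_px=0, width_px=200, height_px=100)


def _frame_with_cell(x, y, rm=4.0, rb=1.5, noise=0.0, seed=0,
                     shape=(100, 220)):
    cell = make_cell(0, mother_radius_um=rm, bud_radius_um=rb)
    return render_frame([(cell, x, y)], shape=shape, noise_sigma=noise,
                        rng=np.random.default_rng(seed))


def test_identical_frames_cancel_exactly():
    f = _frame_with_cell(100, 50)
    assert np.all(subtract_background(f.pixels, f.pixels) == 0)


def test_zero_background_returns_frame():
    f = _frame_with_cell(100, 50)
    diff = subtract_background(f.pixels, np.zeros_like(f.pixels))
    assert np.array_equal(diff, f.pixels)


def test_dimension_mismatch_rejected():
    with pytest.raises(ValueError):
        subtract_background(np.zeros((5, 5)), np.zeros((5, 6)))


def test_static_artifact_cancels_leaving_only_cell():
    # A dirt blob present in both background and frame must vanish.
    artifact = make_cell(1, mother_radius_um=3.0, bud_radius_um=0.0)
    bg = render_frame([(artifact, 60.0, 30.0)], shape=(100, 220),
                      noise_sigma=0.0)
    cell = make_cell(0, mother_radius_um=4.0, bud_radius_um=1.5)
    frame = render_frame([(artifact, 60.0, 30.0), (cell, 150.0, 50.0)],
                         shape=(100, 220), noise_sigma=0.0)
    diff = subtract_background(frame.pixels, bg.pixels)
    _, n = ndimage.label(diff > 15.0)
    assert n == 1


def test_blank_difference_finds_nothing():
    det = scan_for_cell(np.zeros((100, 220)), ROI, threshold=15.0)
    assert not det.found
    assert det.hit_x_px is None and det.hit_y_px is None
    # A full scan visits exactly the strided grid.
    assert det.pixels_visited == 20 * 40  # ceil(100/5) * ceil(200/5)


@pytest.mark.parametrize("seed", range(8))
def test_strided_scan_agrees_with_dense_scan(seed):
    # Cells are 9+ px across, so the stride-5 grid cannot miss one:
    # wherever the cell lands, strided and dense scans agree.
    rng = np.random.default_rng(seed)
    x = rng.uniform(ROI.x_offset_px + 15, ROI.x_offset_px + ROI.width_px - 15)
    y = rng.uniform(15, 85)
    rm = rng.uniform(2.5, 5.0)
    f = _frame_with_cell(x, y, rm=rm, rb=0.0, noise=3.0, seed=seed)
    diff = subtract_background(
        f.pixels, np.full(f.pixels.shape, BACKGROUND_INTENSITY))
    strided = scan_for_cell(diff, ROI, stride=5, threshold=15.0)
    dense = scan_for_cell(diff, ROI, stride=1, threshold=15.0)
    assert strided.found and dense.found
    diameter_px = 2 * rm / 0.562
    for det in (strided, dense):
        assert abs(det.hit_x_px - x) <= diameter_px
        assert abs(det.hit_y_px - y) <= diameter_px


def test_two_cells_hit_belongs_to_upstream_cell():
    a = make_cell(0, mother_radius_um=4.0, bud_radius_um=0.0)
    b = make_cell(1, mother_radius_um=4.0, bud_radius_um=0.0)
    frame = render_frame([(a, 60.0, 50.0), (b, 180.0, 50.0)],
                         shape=(100, 220), noise_sigma=0.0)
    diff = subtract_background(
        frame.pixels, np.full(frame.pixels.shape, BACKGROUND_INTENSITY))
    det = scan_for_cell(diff, ROI, threshold=15.0)
    assert det.found
    assert abs(det.hit_x_px - 60.0) < 2 * 4.0 / 0.562
    # With flow reversed the downstream cell is found first.
    roi_rev = RoiSpec(x_offset_px=10, y_offset_px=0, width_px=200,
                      height_px=100, upstream="right")
    det_rev = scan_for_cell(diff, roi_rev, threshold=15.0)
    assert abs(det_rev.hit_x_px - 180.0) < 2 * 4.0 / 0.562


def test_early_exit_visits_no_downstream_columns():
    diff = np.zeros((100, 220))
    diff[50, 110] = 100.0  # single hot pixel on the strided grid
    det = scan_for_cell(diff, ROI, stride=5, threshold=15.0)
    assert det.found and (det.hit_x_px, det.hit_y_px) == (110, 50)
    cols_before = (110 - ROI.x_offset_px) // 5
    rows_per_col = 20
    assert det.pixels_visited == cols_before * rows_per_col + 50 // 5 + 1
    assert det.pixels_visited <= 20 * 40


def test_bead_mode_threshold_on_maximum_intensity():
    blank = np.full((100, 220), BACKGROUND_INTENSITY)
    assert not detect_particle(blank, ROI, 225.0)
    bead = blank.copy()
    bead[40, 100] = 250.0
    assert detect_particle(bead, ROI, 225.0)


@pytest.mark.parametrize("seed", range(5))
def test_bead_detection_matches_exhaustive_max(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        frame = rng.uniform(180, 230, size=(100, 220))
        thr = rng.uniform(200, 235)
        oracle = max(frame[y, x]
                     for y in range(ROI.y_offset_px,
                                    ROI.y_offset_px + ROI.height_px)
                     for x in range(ROI.x_offset_px,
                                    ROI.x_offset_px + ROI.width_px)) > thr
        assert detect_particle(frame, ROI, thr) == oracle


def test_roi_spec_validation():
    with pytest.raises(ValueError):
        RoiSpec(0, 0, 800, 500)  # 400k px exceeds the camera limit
    roi = RoiSpec(0, 0, 600, 170)
    with pytest.raises(ValueError):
        roi.validate_within((100, 620))  # too short for the ROI height
    with pytest.raises(ValueError):
        scan_for_cell(np.zeros((200, 700)), roi, stride=0)
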