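"""Synthetic imaging: rendering geometry, noise model, stream truth."""

import math

import numpy as np
import pytest
from scipy import ndimage

from budsort.synth import (BACKGROUND_INTENSITY, BUD_NECK_FACTOR,
                           CellTruth, StreamConfig, class_from_ratio,
                           frames_to_uint8, generate_stream,
                           generate_training_set, make_cell, render_cell,
                           render_frame)

PITCH = 0.562


def _two_disk_union_area(r1, r2, d):
    """Closed-form area of the union of two disks at centre distance d."""
    if r2 == 0:
        return math.pi * r1 ** 2
    if d >= r1 + r2:
        lens = 0.0
    elif d <= abs(r1 - r2):
        lens = math.pi * min(r1, r2) ** 2
    else:
        a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
        a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
        a3 = 0.5 * math.sqrt((-d + r1 + r2) * (d + r1 - r2)
                             * (d - r1 + r2) * (d + r1 + r2))
        lens = a1 + a2 - a3
    return math.pi * (r1 ** 2 + r2 ** 2) - lens


def test_class_rule_from_bud_ratio():
    assert class_from_ratio(4.0, 0.0) == 1
    assert class_from_ratio(4.0, 1.2) == 2   # ratio 0.3 -> small bud
    assert class_from_ratio(4.0, 2.0) == 3   # ratio 0.5 is already large
    with pytest.raises(ValueError):
        CellTruth(cell_id=0, mother_radius_um=4.0, bud_radius_um=1.2,
                  true_class=1, velocity_um_s=1000.0)


def test_unbudded_mask_is_single_disk():
    cell = make_cell(0, mother_radius_um=4.0, bud_radius_um=0.0)
    _, mask = render_cell(cell, PITCH)
    r_px = 4.0 / PITCH
    assert mask.sum() == pytest.approx(math.pi * r_px ** 2, rel=0.10)
    _, n = ndimage.label(mask)
    assert n == 1


@pytest.mark.parametrize("rm, rb, angle",
                         [(4.0, 1.2, 0.0), (4.0, 1.2, 2.1), (3.0, 2.0, 0.7),
                          (5.0, 4.0, 4.0), (2.5, 1.0, 1.0)])
def test_mask_area_matches_two_disk_geometry(rm, rb, angle):
    cell = make_cell(0, mother_radius_um=rm, bud_radius_um=rb,
                     bud_angle_rad=angle)
    _, mask = render_cell(cell, PITCH)
    r1, r2 = rm / PITCH, rb / PITCH
    d = r1 + BUD_NECK_FACTOR * r2
    assert mask.sum() == pytest.approx(_two_disk_union_area(r1, r2, d),
                                       rel=0.10)


def test_bud_larger_than_mother_rejected():
    with pytest.raises(ValueError):
        make_cell(0, mother_radius_um=3.0, bud_radius_um=3.5)


def test_empty_noise_free_frame_is_flat_background():
    frame = render_frame([], shape=(64, 80), noise_sigma=0.0)
    assert np.all(frame.pixels == BACKGROUND_INTENSITY)


def test_single_cell_gives_one_dark_region():
    cell = make_cell(0, mother_radius_um=4.0, bud_radius_um=1.5)
    frame = render_frame([(cell, 40.0, 32.0)], shape=(64, 80),
                         noise_sigma=0.0)
    dark = frame.pixels < BACKGROUND_INTENSITY - 10
    _, n = ndimage.label(dark)
    assert n == 1


def test_offcell_noise_matches_half_normal_mean():
    sigma = 5.0
    frame = render_frame([], shape=(340, 340), noise_sigma=sigma,
                         rng=np.random.default_rng(3))
    mad = np.abs(frame.pixels - BACKGROUND_INTENSITY).mean()
    assert mad == pytest.approx(sigma * math.sqrt(2 / math.pi), rel=0.05)


def test_stream_determinism_bit_identical():
    config = StreamConfig(n_cells=5, seed=11, spacing_frames=4.0)
    s1 = generate_stream(config)
    s2 = generate_stream(config)
    assert len(s1.frames) == len(s2.frames)
    assert all(np.array_equal(a.pixels, b.pixels)
               for a, b in zip(s1.frames, s2.frames))
    assert s1.truth.equals(s2.truth)
    assert frames_to_uint8(s1.frames).tobytes() == \
        frames_to_uint8(s2.frames).tobytes()


def test_truth_labels_satisfy_ratio_rule():
    s = generate_stream(StreamConfig(n_cells=40, seed=2, spacing_frames=1.0,
                                     noise_sigma=0.0))
    for c in s.cells:
        assert c.true_class == class_from_ratio(c.mother_radius_um,
                                                c.bud_radius_um)
    # Truth log classes recompute identically from logged radii.
    for _, row in s.truth.iterrows():
        assert row["class"] == class_from_ratio(row["mother_r_um"],
                                                row["bud_r_um"])


def test_six_frame_spacing_keeps_roi_single_occupancy():
    # At >= 6-frame spacing even the slowest cell clears a 220 um
    # detection window before the next cell enters it.
    config = StreamConfig(n_cells=12, seed=3, spacing_frames=6.0,
                          noise_sigma=0.0)
    s = generate_stream(config)
    roi_px = 220.0 / config.pixel_pitch_um
    for _, rows in s.truth.groupby("frame_id"):
        in_roi = rows[(rows["x_px"] >= 0) & (rows["x_px"] < roi_px)]
        assert len(in_roi) <= 1


def test_fixed_velocity_displacement_per_frame():
    config = StreamConfig(n_cells=1, seed=1, noise_sigma=0.0,
                          velocity_range_um_s=(1000.0, 1000.0),
                          frame_interval_ms=63.0)
    s = generate_stream(config)
    xs = s.truth.sort_values("frame_id")["x_px"].to_numpy()
    steps = np.diff(xs) * config.pixel_pitch_um
    assert np.allclose(steps, 63.0)  # 1000 um/s * 63 ms


def test_empty_stream_is_noise_only():
    s = generate_stream(StreamConfig(n_cells=0, seed=1, noise_sigma=0.0))
    assert s.truth.empty
    for f in s.frames:
        assert np.all(f.pixels == BACKGROUND_INTENSITY)


def test_training_set_counts_and_class_bounds():
    patches, labels, truths = generate_training_set(n_per_class=30, seed=0)
    assert len(patches) == 90
    assert [(labels == c).sum() for c in (1, 2, 3)] == [30, 30, 30]
    for t in truths:
        ratio = t.bud_radius_um / t.mother_radius_um
        if t.true_class == 1:
            assert ratio == 0.0
        elif t.true_class == 2:
            assert 0.0 < ratio < 0.5
        else:
            assert ratio >= 0.5
    single = generate_training_set(n_per_class=1, seed=0)
    assert len(single[0]) == 3


def test_config_hash_tracks_config_changes():
    a = StreamConfig(n_cells=5, seed=1)
    b = StreamConfig(n_cells=5, seed=1)
    c = StreamConfig(n_cells=6, seed=1)
    assert a.config_hash() == b.config_hash()
    assert a.config_hash() != c.config_hash()
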