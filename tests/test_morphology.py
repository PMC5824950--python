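"""Segmentation, two-disk feature extraction and the kNN classifier."""

import math

import numpy as np
import pytest

from budsort.morphology import (FeatureVector, SegmentationError, classify,
                                extract_features, features_from_patch,
                                load_model, predict, save_model,
                                segment_cell, train_from_patches, train_knn)
from budsort.synth import (BACKGROUND_INTENSITY, generate_training_set,
                           make_cell, render_frame)

PITCH = 0.562


def _patch(rm, rb, angle=0.0, noise=0.0, seed=0, shape=(64, 64)):
    cell = make_cell(0, mother_radius_um=rm, bud_radius_um=rb,
                     bud_angle_rad=angle)
    f = render_frame([(cell, shape[1] / 2, shape[0] / 2)], shape=shape,
                     noise_sigma=noise, rng=np.random.default_rng(seed))
    return np.abs(f.pixels - BACKGROUND_INTENSITY)


def test_segmented_disk_area_matches_circle():
    diff = _patch(4.0, 0.0)
    seed_pt = (32, 32)
    mask, truncated = segment_cell(diff, seed_pt, threshold=15.0)
    assert not truncated
    r_px = 4.0 / PITCH
    assert mask.sum() == pytest.approx(math.pi * r_px ** 2, rel=0.15)


def test_seed_on_blank_region_raises():
    diff = _patch(4.0, 0.0)
    with pytest.raises(SegmentationError):
        segment_cell(diff, (2, 2), threshold=15.0)


def test_segmentation_respects_connectivity():
    a = make_cell(0, mother_radius_um=4.0, bud_radius_um=0.0)
    b = make_cell(1, mother_radius_um=3.0, bud_radius_um=0.0)
    f = render_frame([(a, 25.0, 32.0), (b, 75.0, 32.0)], shape=(64, 100),
                     noise_sigma=0.0)
    diff = np.abs(f.pixels - BACKGROUND_INTENSITY)
    mask, _ = segment_cell(diff, (32, 25), threshold=15.0)
    assert mask[:, :50].sum() > 0
    assert mask[:, 55:].sum() == 0


def test_border_touching_component_flagged_truncated():
    diff = _patch(4.0, 0.0)
    shifted = np.roll(diff, -30, axis=1)  # push the cell into the border
    mask, truncated = segment_cell(shifted, (32, 2), threshold=15.0)
    assert truncated


def test_single_disk_features():
    # A disk of radius 8 px: mother radius within a pixel, no bud.
    diff = _patch(8 * PITCH, 0.0)
    mask, _ = segment_cell(diff, (32, 32), threshold=15.0)
    fv = extract_features(mask)
    assert fv.mother_radius_px == pytest.approx(8.0, abs=1.0)
    assert fv.bud_ratio == 0.0


@pytest.mark.parametrize("angle", [0.0, 1.0, 2.5, 4.2])
def test_two_disk_ratio_recovery(angle):
    # Mother 8 px, bud 2.4 px: measured bud ratio near the true 0.3.
    fv = features_from_patch(
        _patch(8 * PITCH, 2.4 * PITCH, angle=angle) + BACKGROUND_INTENSITY)
    assert fv.bud_ratio == pytest.approx(0.3, abs=0.08)


def test_batch_ratio_recovery_against_generator_truth():
    _, labels, truths = generate_training_set(n_per_class=15, seed=5,
                                              noise_sigma=0.0)
    patches, _, _ = generate_training_set(n_per_class=15, seed=5,
                                          noise_sigma=0.0)
    errors = []
    for patch, truth in zip(patches, truths):
        if truth.true_class == 1:
            continue
        fv = features_from_patch(patch)
        true_ratio = truth.bud_radius_um / truth.mother_radius_um
        errors.append(fv.bud_ratio - true_ratio)
    assert np.mean(np.abs(errors)) < 0.08


def test_degenerate_single_pixel_mask():
    mask = np.zeros((9, 9), dtype=bool)
    mask[4, 4] = True
    fv = extract_features(mask)
    assert fv.bud_ratio == 0.0
    with pytest.raises(ValueError):
        extract_features(np.zeros((5, 5), dtype=bool))


def _brute_force_knn(model, x, k=3):
    """Oracle: exhaustive distance sort + the same published tie rule."""
    z = model.normalize(np.asarray(x, dtype=float))
    scored = sorted((float(np.linalg.norm(row - z)), i)
                    for i, row in enumerate(model.features))
    nn_labels = [int(model.labels[i]) for _, i in scored[:k]]
    counts = {c: nn_labels.count(c) for c in set(nn_labels)}
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else nn_labels[0]


def test_knn_matches_brute_force_oracle(knn_model):
    rng = np.random.default_rng(0)
    patches, _, _ = generate_training_set(n_per_class=67, seed=21)
    queries = [features_from_patch(p).as_array() for p in patches[:200]]
    for q in queries:
        assert classify(q, knn_model) == _brute_force_knn(knn_model, q)
    # Independent cross-check of the neighbour search itself.
    from sklearn.neighbors import NearestNeighbors
    nn = NearestNeighbors(n_neighbors=3).fit(knn_model.features)
    q = rng.choice(len(queries), size=20, replace=False)
    for i in q:
        z = knn_model.normalize(queries[i])
        sk_idx = set(nn.kneighbors([z], return_distance=False)[0])
        scored = sorted((float(np.linalg.norm(row - z)), j)
                        for j, row in enumerate(knn_model.features))
        assert {j for _, j in scored[:3]} == sk_idx


def test_three_way_tie_resolved_to_nearest_neighbour():
    feats = np.array([[0.0], [1.1], [2.0]])
    model = train_knn(feats, [3, 1, 2], k=1)
    # Rebuild with k=3 manually so each class votes once.
    model3 = train_knn(np.vstack([feats] * 3),
                       [3, 1, 2] * 3, k=3)
    # Query nearest to the class-3 sample: tie (each class can appear
    # once among the 3 nearest) must resolve to class 3.
    assert classify(np.array([0.0]), model3) == 3
    assert classify(np.array([0.0]), model) == 3


def test_training_set_self_match_with_k1():
    patches, labels, _ = generate_training_set(n_per_class=10, seed=9)
    feats = [features_from_patch(p) for p in patches]
    model = train_knn(feats, labels, k=1)
    assert np.array_equal(predict(model, feats), labels)


def test_training_validation():
    feats = np.array([[0.0], [1.0], [2.0], [3.0]])
    with pytest.raises(ValueError):
        train_knn(feats, [1, 1, 1, 2], k=3)  # class 2 has < k samples
    with pytest.raises(ValueError):
        train_knn(feats, [1, 1, 2, 2], k=2)  # even k


def test_classification_invariant_to_translation_and_rotation(knn_model):
    cell = make_cell(0, mother_radius_um=4.0, bud_radius_um=1.3,
                     bud_angle_rad=0.8)
    f = render_frame([(cell, 24.0, 40.0)], shape=(64, 64), noise_sigma=0.0)
    base = classify(features_from_patch(f.pixels), knn_model)
    shifted = np.roll(f.pixels, (5, -7), axis=(0, 1))
    assert classify(features_from_patch(shifted), knn_model) == base
    for rot in range(1, 4):
        rotated = np.rot90(f.pixels, rot)
        assert classify(features_from_patch(rotated), knn_model) == base


def test_model_json_round_trip(tmp_path, knn_model):
    path = tmp_path / "model.json"
    save_model(knn_model, path)
    loaded = load_model(path)
    fv = FeatureVector(area_px=160.0, mother_radius_px=7.0,
                       bud_radius_px=2.1, bud_ratio=0.3, eccentricity=0.5)
    assert classify(fv, loaded) == classify(fv, knn_model)
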