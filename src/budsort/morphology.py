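"""Cell segmentation, feature extraction and kNN morphology classing.

A detected cell is isolated as the connected component of
above-threshold difference pixels containing the scan hit, holes
filled.  Features come from a two-disk decomposition of the mask: the
largest inscribed disk (the Euclidean distance-transform maximum) is
the mother, the largest disk inscribed in the residual — if the
residual is more than a few pixels — is the bud.  The bud-to-mother
radius ratio is the discriminative feature separating the three
morphology classes (unbudded / small bud, ratio < 0.5 / large bud);
area and eccentricity add robustness when the bud is barely resolved.

Classification is a self-trained k-nearest-neighbour vote (k = 3) on
z-normalized features, with three-way ties resolved to the single
nearest neighbour's class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .synth import BACKGROUND_INTENSITY

#: Residual blobs below this area (px^2) are not buds.  At the default
#: pixel pitch a just-resolvable bud leaves a ~4 px^2 residual, while
#: with a 5-sigma detection threshold a false noise pixel is already a
#: <1e-6 per-pixel event, so 3 px^2 suppresses noise without discarding
#: real small buds.
MIN_BUD_AREA_PX = 3

#: The bud disk centre sits at mother_radius + 0.6 * bud_radius, so the
#: largest disk inscribed in the residual (bud minus mother) has radius
#: 0.8 * bud_radius; this factor undoes that geometric bias.
NECK_OVERLAP_CORRECTION = 1.25


class SegmentationError(ValueError):
    """Raised when no cell component exists at the seed point."""


@dataclass(frozen=True)
class FeatureVector:
    """Geometric features of one segmented cell."""

    area_px: float
    mother_radius_px: float
    bud_radius_px: float
    bud_ratio: float
    eccentricity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.area_px, self.mother_radius_px,
                         self.bud_radius_px, self.bud_ratio,
                         self.eccentricity], dtype=float)


FEATURE_NAMES = ("area_px", "mother_radius_px", "bud_radius_px",
                 "bud_ratio", "eccentricity")


def segment_cell(diff: np.ndarray, seed_yx: Tuple[int, int],
                 threshold: float = 15.0) -> Tuple[np.ndarray, bool]:
    """Isolate the cell under the seed point.

    Returns ``(mask, truncated)``: the hole-filled connected component
    of above-threshold pixels containing the seed, and a flag set when
    the component touches the image border (cell partially out of
    view, so its features are unreliable).
    """
    seed_yx = (int(seed_yx[0]), int(seed_yx[1]))
    binary = diff > threshold
    if not binary[seed_yx]:
        raise SegmentationError(f"no cell at seed point {seed_yx}")
    labels, _ = ndimage.label(binary)
    mask = labels == labels[seed_yx]
    mask = ndimage.binary_fill_holes(mask)
    # The detection threshold sits low on the blurred rim, which
    # dilates the component; the blurred edge crosses half the cell
    # contrast exactly at the true boundary, so refine there.
    peak = float(diff[mask].max())
    refine_thr = max(threshold, 0.5 * peak)
    refined = mask & (diff > refine_thr)
    if refined.any():
        rlabels, n = ndimage.label(refined)
        sizes = ndimage.sum_labels(refined, rlabels, index=range(1, n + 1))
        mask = rlabels == (int(np.argmax(sizes)) + 1)
        mask = ndimage.binary_fill_holes(mask)
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    truncated = bool(rows[0] or rows[-1] or cols[0] or cols[-1])
    return mask, truncated


def extract_features(mask: np.ndarray) -> FeatureVector:
    """Two-disk decomposition of a cell mask into mother and bud.

    The mother is the largest inscribed disk (EDT maximum); pixels
    outside it form the residual, whose largest connected blob — if at
    least :data:`MIN_BUD_AREA_PX` — is the bud.  Degenerate masks
    (single pixels, no residual) yield ``bud_ratio = 0``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    area = float(mask.sum())
    edt = ndimage.distance_transform_edt(mask)
    mother_r = float(edt.max())
    cy, cx = np.unravel_index(int(np.argmax(edt)), edt.shape)
    yy, xx = np.ogrid[0:mask.shape[0], 0:mask.shape[1]]
    mother_disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= mother_r ** 2
    residual = mask & ~mother_disk
    bud_r = 0.0
    if residual.sum() >= MIN_BUD_AREA_PX:
        labels, n = ndimage.label(residual)
        sizes = ndimage.sum_labels(residual, labels, index=range(1, n + 1))
        biggest = int(np.argmax(sizes)) + 1
        if sizes[biggest - 1] >= MIN_BUD_AREA_PX:
            blob = labels == biggest
            blob_edt = ndimage.distance_transform_edt(blob)
            bud_r = float(blob_edt.max()) * NECK_OVERLAP_CORRECTION
            bud_r = min(bud_r, mother_r)
    props = regionprops(mask.astype(np.uint8))[0]
    return FeatureVector(
        area_px=area,
        mother_radius_px=mother_r,
        bud_radius_px=bud_r,
        bud_ratio=bud_r / mother_r if mother_r > 0 else 0.0,
        eccentricity=float(props.eccentricity),
    )


def features_from_patch(patch: np.ndarray,
                        background: float = BACKGROUND_INTENSITY,
                        threshold: float = 15.0) -> FeatureVector:
    """Detection-free pipeline for an isolated cell patch: difference
    against a flat background, seed at the strongest pixel, segment,
    extract."""
    diff = np.abs(np.asarray(patch, dtype=float) - background)
    seed = np.unravel_index(int(np.argmax(diff)), diff.shape)
    mask, _ = segment_cell(diff, seed, threshold)
    return extract_features(mask)


@dataclass
class KnnModel:
    """kNN classifier state: z-normalized training features + labels."""

    features: np.ndarray        # (n, d), normalized
    labels: np.ndarray          # (n,)
    k: int
    loc: np.ndarray             # per-feature mean used for normalization
    scale: np.ndarray           # per-feature std (1 where degenerate)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.loc) / self.scale


def train_knn(samples: Sequence[FeatureVector] | np.ndarray,
              labels: Sequence[int], k: int = 3) -> KnnModel:
    """Fit the classifier: store z-scaled features and labels.

    Requires an odd ``k`` and at least ``k`` samples in every class.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd number")
    X = np.asarray([s.as_array() if isinstance(s, FeatureVector) else s
                    for s in samples], dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise ValueError("samples and labels length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        lacking = classes[counts < k]
        raise ValueError(f"classes {lacking.tolist()} have fewer than "
                         f"k={k} training samples")
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return KnnModel(features=(X - loc) / scale, labels=y, k=k,
                    loc=loc, scale=scale)


def classify(features: FeatureVector | np.ndarray, model: KnnModel) -> int:
    """Majority vote among the k nearest training samples.

    Euclidean distance in normalized feature space; neighbours are
    ordered by (distance, training index) so the vote is fully
    deterministic.  A tie between classes (one vote each for k = 3) is
    resolved to the class of the single nearest neighbour.
    """
    x = features.as_array() if isinstance(features, FeatureVector) \
        else np.asarray(features, dtype=float)
    z = model.normalize(x)
    d = np.sqrt(((model.features - z) ** 2).sum(axis=1))
    order = np.lexsort((np.arange(len(d)), d))
    nn = order[:model.k]
    votes = model.labels[nn]
    classes, counts = np.unique(votes, return_counts=True)
    winners = classes[counts == counts.max()]
    if len(winners) == 1:
        return int(winners[0])
    return int(model.labels[nn[0]])


def predict(model: KnnModel,
            samples: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    return np.asarray([classify(s, model) for s in samples], dtype=int)


def classify_patches(patches: Sequence[np.ndarray], model: KnnModel,
                     threshold: float = 15.0) -> np.ndarray:
    """Segment + featurize + classify a batch of isolated cell patches."""
    return np.asarray(
        [classify(features_from_patch(p, threshold=threshold), model)
         for p in patches], dtype=int)


def train_from_patches(patches: Sequence[np.ndarray],
                       labels: Sequence[int], k: int = 3,
                       threshold: float = 15.0) -> KnnModel:
    feats = [features_from_patch(p, threshold=threshold) for p in patches]
    return train_knn(feats, labels, k=k)


def save_model(model: KnnModel, path: str | Path) -> None:
    """Serialize a trained model to a documented JSON file."""
    payload = {
        "feature_names": list(FEATURE_NAMES),
        "k": model.k,
        "loc": model.loc.tolist(),
        "scale": model.scale.tolist(),
        "features": model.features.tolist(),
        "labels": model.labels.tolist(),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def load_model(path: str | Path) -> KnnModel:
    d = json.loads(Path(path).read_text())
    return KnnModel(features=np.asarray(d["features"], dtype=float),
                    labels=np.asarray(d["labels"], dtype=int),
                    k=int(d["k"]),
                    loc=np.asarray(d["loc"], dtype=float),
                    scale=np.asarray(d["scale"], dtype=float))
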