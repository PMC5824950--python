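"""Synthetic micrograph stream generator with ground truth.

Emulates single budding yeast cells (5–10 μm diameter, three
morphology classes) carried through a microchannel and imaged in
brightfield, plus a fluorescent-bead mode.  Cells are rendered as dark
two-disk figures — a mother disk and, for budded cells, a tangent,
slightly overlapping bud disk — on a light background, with a 1 px
Gaussian rim blur.  This is deliberately not photorealistic: it
reproduces exactly the structure the detection and classification
pipeline relies on (contrast against a static background, disk
geometry, bud-to-mother radius ratio) so that every downstream stage
can be tested against known truth without any external data.

Morphology classes follow the bud-ratio rule:

* class 1 — unbudded (bud radius 0),
* class 2 — small bud, bud/mother radius ratio in (0, 0.5),
* class 3 — large bud, ratio >= 0.5.

Everything is driven by a single integer seed; the same configuration
yields bit-identical frames and truth logs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import gaussian_filter

from .geometry import ChannelGeometry, DEFAULT_GEOMETRY

# Fixed 8-bit intensity model: light background, dark cells, bright beads.
MAX_INTENSITY = 255.0
BACKGROUND_INTENSITY = 200.0
CELL_CONTRAST = 80.0        # cells are this much darker than background
BEAD_CONTRAST = 55.0        # beads are this much brighter than background
EDGE_BLUR_SIGMA = 1.0       # px, Gaussian rim blur

#: Default pixel pitch, μm per pixel (≈1600 px across a 900 μm field).
DEFAULT_PITCH_UM_PER_PX = 0.562

#: Bud-disk centre offset from the mother centre, in units of
#: (mother_radius + this factor * bud_radius); < 1 so the disks overlap
#: and form a neck.
BUD_NECK_FACTOR = 0.6

MOTHER_RADIUS_RANGE_UM = (2.5, 5.0)
VELOCITY_RANGE_UM_S = (600.0, 2000.0)

# Class-conditional bud-ratio sampling ranges.  Class 2 starts at 0.15:
# below that the bud is a sub-pixel emergent bump at the default pitch
# and the cell is morphologically indistinguishable from unbudded.
CLASS2_RATIO_RANGE = (0.15, 0.45)
CLASS3_RATIO_RANGE = (0.50, 0.90)


def class_from_ratio(mother_radius_um: float, bud_radius_um: float) -> int:
    """Morphology class from the bud-to-mother radius ratio."""
    if bud_radius_um == 0:
        return 1
    return 2 if bud_radius_um / mother_radius_um < 0.5 else 3


@dataclass(frozen=True)
class CellTruth:
    """Generator-side ground truth for one cell."""

    cell_id: int
    mother_radius_um: float
    bud_radius_um: float
    true_class: int
    velocity_um_s: float
    t_enter_ms: float = 0.0       # instant the centre crosses x = 0
    y_offset_px: float = 0.0      # residual off-axis position after focusing
    bud_angle_rad: float = 0.0
    fluorescent: bool = False

    def __post_init__(self) -> None:
        if self.mother_radius_um <= 0:
            raise ValueError("mother_radius_um must be positive")
        if self.bud_radius_um < 0:
            raise ValueError("bud_radius_um must be >= 0")
        if self.bud_radius_um > self.mother_radius_um:
            raise ValueError("bud larger than mother is not a valid "
                             "budding configuration")
        expected = class_from_ratio(self.mother_radius_um, self.bud_radius_um)
        if self.true_class != expected:
            raise ValueError(
                f"true_class {self.true_class} inconsistent with radii "
                f"(expected {expected})")
        if self.velocity_um_s <= 0:
            raise ValueError("velocity_um_s must be positive")

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.mother_radius_um

    def x_um(self, t_ms: float) -> float:
        """Centre position along the channel axis at time ``t_ms``."""
        return (t_ms - self.t_enter_ms) * self.velocity_um_s / 1000.0


def make_cell(cell_id: int, mother_radius_um: float, bud_radius_um: float,
              velocity_um_s: float = 1000.0, **kwargs) -> CellTruth:
    """Construct a :class:`CellTruth` with the class derived from radii."""
    return CellTruth(
        cell_id=cell_id,
        mother_radius_um=mother_radius_um,
        bud_radius_um=bud_radius_um,
        true_class=class_from_ratio(mother_radius_um, bud_radius_um),
        velocity_um_s=velocity_um_s,
        **kwargs,
    )


@dataclass(frozen=True)
class Frame:
    """One acquired image with its metadata."""

    pixels: np.ndarray            # 2-D float array, values in [0, 255]
    timestamp_ms: float
    pixel_pitch_um: float = DEFAULT_PITCH_UM_PER_PX
    frame_id: int = 0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


def render_cell(truth: CellTruth,
                pitch_um_per_px: float = DEFAULT_PITCH_UM_PER_PX
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Render one cell into a small patch centred on the mother disk.

    Returns ``(patch, mask)`` where ``patch`` is the intensity image
    (background everywhere except the blurred cell figure) and ``mask``
    is the exact, unblurred union of the mother and bud disks.
    """
    if truth.bud_radius_um > truth.mother_radius_um:
        raise ValueError("bud larger than mother is not a valid "
                         "budding configuration")
    rm = truth.mother_radius_um / pitch_um_per_px
    rb = truth.bud_radius_um / pitch_um_per_px
    margin = 3.0 + 3.0 * EDGE_BLUR_SIGMA
    half = int(math.ceil(rm + (BUD_NECK_FACTOR + 1.0) * rb + margin))
    size = 2 * half + 1
    cy = cx = float(half)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= rm ** 2
    if rb > 0:
        sep = rm + BUD_NECK_FACTOR * rb
        bx = cx + sep * math.cos(truth.bud_angle_rad)
        by = cy + sep * math.sin(truth.bud_angle_rad)
        mask |= (yy - by) ** 2 + (xx - bx) ** 2 <= rb ** 2
    contrast = BEAD_CONTRAST if truth.fluorescent else -CELL_CONTRAST
    patch = np.full((size, size), BACKGROUND_INTENSITY, dtype=float)
    patch[mask] += contrast
    patch = gaussian_filter(patch, EDGE_BLUR_SIGMA)
    return patch, mask


def render_frame(placements: Sequence[Tuple[CellTruth, float, float]],
                 shape: Tuple[int, int] = (170, 660),
                 noise_sigma: float = 3.0,
                 rng: Optional[np.random.Generator] = None,
                 pitch_um_per_px: float = DEFAULT_PITCH_UM_PER_PX,
                 frame_id: int = 0,
                 timestamp_ms: float = 0.0) -> Frame:
    """Compose a frame from cell placements plus Gaussian sensor noise.

    ``placements`` holds ``(truth, x_px, y_px)`` centre positions.
    Cell figures add their deviation from background, so overlapping
    cells darken additively (overlaps are legal — they are what
    produces miss-sorting downstream) and static artifacts shared with
    the background cancel exactly under background subtraction.
    """
    canvas = np.full(shape, BACKGROUND_INTENSITY, dtype=float)
    for truth, x_px, y_px in placements:
        patch, _ = render_cell(truth, pitch_um_per_px)
        half = patch.shape[0] // 2
        r0 = int(round(y_px)) - half
        c0 = int(round(x_px)) - half
        r1, c1 = r0 + patch.shape[0], c0 + patch.shape[1]
        fr0, fc0 = max(r0, 0), max(c0, 0)
        fr1, fc1 = min(r1, shape[0]), min(c1, shape[1])
        if fr0 >= fr1 or fc0 >= fc1:
            continue
        canvas[fr0:fr1, fc0:fc1] += (
            patch[fr0 - r0:fr1 - r0, fc0 - c0:fc1 - c0]
            - BACKGROUND_INTENSITY)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        canvas = canvas + rng.normal(0.0, noise_sigma, size=shape)
    np.clip(canvas, 0.0, MAX_INTENSITY, out=canvas)
    return Frame(pixels=canvas, timestamp_ms=timestamp_ms,
                 pixel_pitch_um=pitch_um_per_px, frame_id=frame_id)


@dataclass(frozen=True)
class StreamConfig:
    """Everything that determines a synthetic stream.

    ``spacing_frames`` is the inter-cell arrival spacing in frames;
    with ``spacing_mode='exponential'`` it is the mean of an
    exponential inter-arrival distribution instead of a fixed gap.
    The frame interval defaults to the design loop delay (63 ms for
    the 600 × 170 px camera ROI).
    """

    n_cells: int = 20
    class_probabilities: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    velocity_range_um_s: Tuple[float, float] = VELOCITY_RANGE_UM_S
    spacing_frames: float = 8.0
    spacing_mode: str = "fixed"  # fixed | exponential
    noise_sigma: float = 3.0
    seed: int = 0
    frame_shape: Tuple[int, int] = (170, 660)
    pixel_pitch_um: float = DEFAULT_PITCH_UM_PER_PX
    frame_interval_ms: float = 63.0
    fluorescent: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        p = np.asarray(self.class_probabilities, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not math.isclose(
                float(p.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("class_probabilities must be a 3-vector "
                             "summing to 1")
        if self.spacing_mode not in ("fixed", "exponential"):
            raise ValueError("spacing_mode must be 'fixed' or 'exponential'")
        if self.spacing_frames < 0:
            raise ValueError("spacing_frames must be >= 0")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_probabilities"] = list(self.class_probabilities)
        d["velocity_range_um_s"] = list(self.velocity_range_um_s)
        d["frame_shape"] = list(self.frame_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StreamConfig":
        d = dict(d)
        for key in ("class_probabilities", "velocity_range_um_s",
                    "frame_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class Stream:
    """A rendered frame sequence with its ground truth."""

    frames: List[Frame]
    truth: pd.DataFrame
    cells: List[CellTruth]
    config: StreamConfig
    background: Frame = field(repr=False, default=None)


def _sample_cell(cell_id: int, cls: int, rng: np.random.Generator,
                 config: StreamConfig, t_enter_ms: float) -> CellTruth:
    rm = rng.uniform(*MOTHER_RADIUS_RANGE_UM)
    if config.fluorescent:
        # Beads: small bright monodisperse spheres, no morphology.
        rm = rng.uniform(2.0, 2.5)
        rb = 0.0
        cls = 1
    elif cls == 1:
        rb = 0.0
    elif cls == 2:
        rb = rm * rng.uniform(*CLASS2_RATIO_RANGE)
    else:
        rb = rm * rng.uniform(*CLASS3_RATIO_RANGE)
    return CellTruth(
        cell_id=cell_id,
        mother_radius_um=rm,
        bud_radius_um=rb,
        true_class=class_from_ratio(rm, rb),
        velocity_um_s=rng.uniform(*config.velocity_range_um_s),
        t_enter_ms=t_enter_ms,
        y_offset_px=rng.uniform(-2.0, 2.0),
        bud_angle_rad=rng.uniform(0.0, 2.0 * math.pi),
        fluorescent=config.fluorescent,
    )


def sample_cells(config: StreamConfig,
                 rng: Optional[np.random.Generator] = None
                 ) -> List[CellTruth]:
    """Draw the cell population and arrival schedule for a stream."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    classes = rng.choice([1, 2, 3], size=config.n_cells,
                         p=list(config.class_probabilities))
    cells = []
    t = 0.0
    for i in range(config.n_cells):
        if i > 0:
            gap = (config.spacing_frames if config.spacing_mode == "fixed"
                   else rng.exponential(config.spacing_frames))
            t += gap * config.frame_interval_ms
        cells.append(_sample_cell(i, int(classes[i]), rng, config, t))
    return cells

TRUTH_COLUMNS = ["frame_id", "cell_id", "x_px", "y_px", "mother_r_um",
                 "bud_r_um", "class", "velocity_um_s"]


def generate_stream(config: StreamConfig,
                    geometry: ChannelGeometry = DEFAULT_GEOMETRY
                    ) -> Stream:
    """Render the full frame sequence for a configuration.

    Cells enter at the upstream (left) edge and advance by
    velocity × frame_interval per frame; the truth log records the
    per-frame pixel position of every cell visible in each frame.
    Cells sit at the channel mid-height (flow focusing keeps them in a
    single file) with a small fixed per-cell off-axis offset.
    """
    rng = np.random.default_rng(config.seed)
    cells = sample_cells(config, rng)
    h, w = config.frame_shape
    width_um = w * config.pixel_pitch_um
    mid_y = h / 2.0

    if cells:
        last_exit = max(c.t_enter_ms + 1000.0 *
                        (width_um + c.diameter_um) / c.velocity_um_s
                        for c in cells)
        n_frames = int(math.ceil(last_exit / config.frame_interval_ms)) + 1
    else:
        n_frames = 10

    frames: List[Frame] = []
    rows = []
    background = render_frame([], shape=config.frame_shape, noise_sigma=0.0,
                              pitch_um_per_px=config.pixel_pitch_um,
                              frame_id=-1, timestamp_ms=-1.0)
    for k in range(n_frames):
        t = k * config.frame_interval_ms
        placements = []
        for c in cells:
            x_um = c.x_um(t)
            if -c.diameter_um <= x_um <= width_um + c.diameter_um:
                x_px = x_um / config.pixel_pitch_um
                y_px = mid_y + c.y_offset_px
                placements.append((c, x_px, y_px))
                if 0 <= x_um < width_um:
                    rows.append((k, c.cell_id, x_px, y_px,
                                 c.mother_radius_um, c.bud_radius_um,
                                 c.true_class, c.velocity_um_s))
        frames.append(render_frame(
            placements, shape=config.frame_shape,
            noise_sigma=config.noise_sigma, rng=rng,
            pitch_um_per_px=config.pixel_pitch_um,
            frame_id=k, timestamp_ms=t))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return Stream(frames=frames, truth=truth, cells=cells, config=config,
                  background=background)


def generate_training_set(n_per_class: int = 30, seed: int = 0,
                          noise_sigma: float = 3.0,
                          pitch_um_per_px: float = DEFAULT_PITCH_UM_PER_PX,
                          patch_shape: Tuple[int, int] = (64, 64)
                          ) -> Tuple[List[np.ndarray], np.ndarray,
                                     List[CellTruth]]:
    """Labeled single-cell patches, ``n_per_class`` per morphology class.

    Returns ``(patches, labels, truths)``; each patch is an isolated
    cell centred in a noisy background patch, rendered with the same
    model as the stream generator.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    patches: List[np.ndarray] = []
    labels = []
    truths: List[CellTruth] = []
    config = StreamConfig(noise_sigma=noise_sigma, seed=seed,
                          pixel_pitch_um=pitch_um_per_px)
    for cls in (1, 2, 3):
        for i in range(n_per_class):
            truth = _sample_cell(len(truths), cls, rng, config, 0.0)
            frame = render_frame(
                [(truth, patch_shape[1] / 2.0, patch_shape[0] / 2.0)],
                shape=patch_shape, noise_sigma=noise_sigma, rng=rng,
                pitch_um_per_px=pitch_um_per_px)
            patches.append(frame.pixels)
            labels.append(cls)
            truths.append(truth)
    return patches, np.asarray(labels), truths


# ---------------------------------------------------------------------------
# Disk I/O: TIFF/PNG frame stacks, CSV truth log, YAML config, JSON manifest.

def frames_to_uint8(frames: Sequence[Frame]) -> np.ndarray:
    return np.stack([np.clip(np.rint(f.pixels), 0, 255).astype(np.uint8)
                     for f in frames])


def write_stream(stream: Stream, outdir: str | Path,
                 image_format: str = "tiff") -> dict:
    """Write frames, truth log, config and manifest; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = frames_to_uint8(stream.frames)
    if image_format == "tiff":
        frames_path = outdir / "frames.tif"
        tifffile.imwrite(frames_path, stack)
    elif image_format == "png":
        from PIL import Image
        frames_path = outdir / "frames"
        frames_path.mkdir(exist_ok=True)
        for i, page in enumerate(stack):
            Image.fromarray(page).save(frames_path / f"frame_{i:05d}.png")
    else:
        raise ValueError("image_format must be 'tiff' or 'png'")
    truth_path = outdir / "truth.csv"
    stream.truth.to_csv(truth_path, index=False)
    config_path = outdir / "stream_config.yaml"
    config_path.write_text(yaml.safe_dump(stream.config.to_dict(),
                                          sort_keys=True))
    manifest = {
        "seed": stream.config.seed,
        "config_sha256": stream.config.config_hash(),
        "n_frames": len(stream.frames),
        "n_cells": len(stream.cells),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return {"frames": str(frames_path), "truth": str(truth_path),
            "config": str(config_path), "manifest": str(manifest_path)}


def read_config(path: str | Path) -> StreamConfig:
    return StreamConfig.from_dict(yaml.safe_load(Path(path).read_text()))
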