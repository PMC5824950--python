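"""Loop-delay model of the sorting program.

One pass of the sorting loop is: acquire a frame, scan the ROI for a
cell and, when one is found, extract features, classify, and actuate
the valves.  Acquisition adds a fixed delay, scanning costs time
proportional to the ROI pixel count, and classification runs only on
frames that actually contain a cell, so its cost amortizes over the
typical cell arrival rate (about one cell every ten frames).

The same constants drive both the static delay table and the frame
clock of the transport simulator (:mod:`budsort.transport`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import pandas as pd

#: ROI sizes (width × height in pixels) tabulated for the stock camera.
DEFAULT_ROI_SIZES: Tuple[Tuple[int, int], ...] = (
    (1200, 170),
    (1000, 170),
    (600, 170),
    (340, 170),
    (170, 170),
)

#: Camera constraint: ROIs above this pixel count cannot sustain the
#: camera's maximum frame rate.
MAX_ROI_PIXELS = 320_000


@dataclass(frozen=True)
class TimingParams:
    """Delay constants of the sorting loop.

    acquisition_ms
        Fixed image-acquisition overhead per frame (33 ms).
    classification_ms
        Feature extraction + classification when a cell is found (35 ms).
    cell_every_n_frames
        Assumed cell arrival rate used to amortize classification cost.
    scan_rate_px_per_ms
        Effective detection-scan throughput (~4000 ROI pixels per ms,
        already accounting for the stride-5 subsampling).
    """

    acquisition_ms: float = 33.0
    classification_ms: float = 35.0
    cell_every_n_frames: int = 10
    scan_rate_px_per_ms: float = 4000.0

    def __post_init__(self) -> None:
        if min(self.acquisition_ms, self.classification_ms,
               self.scan_rate_px_per_ms) <= 0:
            raise ValueError("timing constants must be positive")
        if self.cell_every_n_frames < 1:
            raise ValueError("cell_every_n_frames must be >= 1")

    @property
    def amortized_classification_ms(self) -> float:
        """Average per-loop classification cost (35 / 10 = 3.5 ms)."""
        return self.classification_ms / self.cell_every_n_frames


DEFAULT_TIMING = TimingParams()


def scan_time_ms(roi_pixels: int, params: TimingParams = DEFAULT_TIMING) -> int:
    """Worst-case time to scan a ROI of ``roi_pixels`` pixels, whole ms.

    The scan aborts at the first cell pixel, so this is the cost of an
    empty frame (the whole ROI is visited).  Rounded up to whole ms.
    """
    if roi_pixels < 0:
        raise ValueError("roi_pixels must be >= 0")
    return math.ceil(roi_pixels / params.scan_rate_px_per_ms - 1e-9)


def loop_delays(roi_pixels: int,
                params: TimingParams = DEFAULT_TIMING) -> Tuple[int, int]:
    """Return ``(worst_case_ms, average_ms)`` for one loop.

    Worst case: acquisition + full classification + full scan (a cell
    found at the very end of the ROI).  Average: acquisition + amortized
    classification + full scan, rounded up to whole ms.
    """
    scan = scan_time_ms(roi_pixels, params)
    worst = math.ceil(params.acquisition_ms + params.classification_ms
                      + scan - 1e-9)
    average = math.ceil(params.acquisition_ms
                        + params.amortized_classification_ms + scan - 1e-9)
    return worst, average


def frame_rate_fps(average_ms: float) -> float:
    """Frames per second for a given average loop delay, truncated to
    one decimal place (63 ms -> 15.8 fps)."""
    if average_ms <= 0:
        raise ValueError("average_ms must be positive")
    return math.floor(10000.0 / average_ms + 1e-9) / 10.0


def timing_table(roi_sizes: Iterable[Sequence[int]] = DEFAULT_ROI_SIZES,
                 params: TimingParams = DEFAULT_TIMING) -> pd.DataFrame:
    """Tabulate scan/worst/average delays and frame rate per ROI size.

    ``roi_sizes`` is an iterable of (width_px, height_px) pairs.
    """
    rows = []
    for w, h in roi_sizes:
        px = int(w) * int(h)
        worst, avg = loop_delays(px, params)
        rows.append({
            "roi_width_px": int(w),
            "roi_height_px": int(h),
            "roi_pixels": px,
            "scan_ms": scan_time_ms(px, params),
            "worst_case_ms": worst,
            "average_ms": avg,
            "frame_rate_fps": frame_rate_fps(avg),
        })
    return pd.DataFrame(rows)
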