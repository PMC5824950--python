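"""End-to-end orchestration: generate → sort → report.

The frames-in path composes the whole loop the way the real program
runs it — acquire, background-subtract, strided scan, segment,
classify, actuate — over a synthetic frame stream, then replays the
collected cells in reverse mode and summarizes classification and
sorting statistics.  The frame clock uses the generator's fixed frame
interval (the design average loop delay); actuation completion adds
the full classification delay plus the mechanical valve latency, and
routing is resolved against each cell's truth trajectory exactly as in
:mod:`budsort.transport`.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import metrics
from .controller import (CellTracker, Route, SorterState, WASTE,
                         on_cell_classified, route_for_class, set_mode)
from .detection import (Detection, RoiSpec, default_threshold,
                        scan_for_cell, subtract_background)
from .geometry import ChannelGeometry, DEFAULT_GEOMETRY
from .morphology import (KnnModel, SegmentationError, classify,
                         extract_features, segment_cell,
                         train_from_patches)
from .synth import (Stream, StreamConfig, generate_stream,
                    generate_training_set, write_stream)
from .timing import DEFAULT_TIMING, TimingParams
from .transport import (DEFAULT_LATENCY_MAX_MS, transit_time_ms,
                        _route_name)

#: Default camera ROI: 600 × 170 px starting 30 px into the frame.
DEFAULT_ROI = RoiSpec(x_offset_px=30, y_offset_px=0,
                      width_px=600, height_px=170)

#: Floor on the detection threshold so that a noise-free stream does
#: not trigger on the far tails of the rendered rim blur.
MIN_THRESHOLD = 5.0


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full generate→sort→report run."""

    stream: StreamConfig = field(default_factory=StreamConfig)
    roi: RoiSpec = DEFAULT_ROI
    timing: TimingParams = DEFAULT_TIMING
    geometry: ChannelGeometry = DEFAULT_GEOMETRY
    latency_max_ms: float = DEFAULT_LATENCY_MAX_MS
    forward_loops: int = 300
    reverse_loops: int = 300
    training_seed: int = 1234
    threshold: Optional[float] = None

    def resolve_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return max(default_threshold(self.stream.noise_sigma),
                   MIN_THRESHOLD)


def train_default_model(seed: int = 1234, noise_sigma: float = 3.0,
                        n_per_class: int = 30,
                        threshold: float = 15.0) -> KnnModel:
    """Self-trained classifier: 30 synthetic samples per class, k = 3."""
    patches, labels, _ = generate_training_set(
        n_per_class=n_per_class, seed=seed, noise_sigma=noise_sigma)
    return train_from_patches(patches, labels, threshold=threshold)


def run_forward(stream: Stream, model: KnnModel, config: RunConfig,
                ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the sorting loop over a frame stream.

    Returns ``(cell_events, actuation_log)``: one row per injected
    cell with its detection/classification/routing outcome, and the
    valve actuation log.
    """
    threshold = config.resolve_threshold()
    rng = np.random.default_rng(config.stream.seed + 77)
    tracker = CellTracker(upstream=config.roi.upstream)
    state = set_mode(SorterState(), "forward")
    truth_by_frame = dict(tuple(stream.truth.groupby("frame_id")))

    switch_times: List[float] = [-math.inf]
    switch_routes: List[Route] = [WASTE]
    detections = []  # (cell_id, t_ms, frame_id, pred, truncated)
    actuation_rows = []

    frames = stream.frames[:config.forward_loops]
    bg = stream.background.pixels
    for frame in frames:
        diff = subtract_background(frame.pixels, bg)
        det: Detection = scan_for_cell(diff, config.roi,
                                       threshold=threshold,
                                       frame_id=frame.frame_id)
        if not (det.found and tracker.observe(det.found, det.hit_x_px)):
            continue
        try:
            mask, truncated = segment_cell(
                diff, (det.hit_y_px, det.hit_x_px), threshold)
            pred = classify(extract_features(mask), model)
        except (SegmentationError, ValueError):
            continue
        state, actuated = on_cell_classified(state, pred)
        t = frame.timestamp_ms
        # Attribute the hit to the nearest truth cell in this frame.
        rows = truth_by_frame.get(frame.frame_id)
        cell_id = -1
        if rows is not None and len(rows):
            j = (rows["x_px"] - det.hit_x_px).abs().idxmin()
            cell_id = int(rows.loc[j, "cell_id"])
        if actuated:
            latency = rng.uniform(0.0, config.latency_max_ms) \
                if config.latency_max_ms > 0 else 0.0
            completion = t + config.timing.classification_ms + latency
            route = route_for_class(pred)
            switch_times.append(completion)
            switch_routes.append(route)
            for valve_id, new_state in (("valve1", route.valve1),
                                        ("valve2", route.valve2)):
                actuation_rows.append({
                    "time_ms": round(completion, 6),
                    "valve_id": valve_id,
                    "new_state": new_state,
                    "cause_cell_id": cell_id,
                })
        detections.append((cell_id, t, frame.frame_id, pred, truncated))

    order = np.argsort(switch_times, kind="stable")
    times_sorted = [switch_times[i] for i in order]
    routes_sorted = [switch_routes[i] for i in order]

    first_detection = {}
    for cell_id, t, frame_id, pred, truncated in detections:
        if cell_id >= 0 and cell_id not in first_detection:
            first_detection[cell_id] = (t, frame_id, pred, truncated)

    rows = []
    for c in stream.cells:
        det_info = first_detection.get(c.cell_id)
        if det_info is not None:
            t_det, frame_id, pred, truncated = det_info
            t_junction = t_det + transit_time_ms(
                config.geometry.roi_to_junction_um, c.velocity_um_s)
            route = routes_sorted[bisect_right(times_sorted, t_junction) - 1]
            routed_to = _route_name(route)
        else:
            t_det = t_junction = math.nan
            frame_id, pred, truncated = -1, 0, False
            routed_to = "missed"
        rows.append({
            "cell_id": c.cell_id,
            "true_class": c.true_class,
            "predicted_class": pred,
            "identified": det_info is not None,
            "detected_frame": frame_id,
            "t_detected_ms": t_det,
            "t_junction_ms": t_junction,
            "truncated": truncated,
            "routed_to": routed_to,
            "sorted_as_predicted": (
                det_info is not None
                and routed_to == _route_name(route_for_class(pred))),
            "velocity_um_s": c.velocity_um_s,
        })
    cell_events = pd.DataFrame(rows)
    actuation_log = pd.DataFrame(
        actuation_rows,
        columns=["time_ms", "valve_id", "new_state", "cause_cell_id"])
    return cell_events, actuation_log


def run_reverse(stream: Stream, cell_events: pd.DataFrame,
                config: RunConfig) -> pd.DataFrame:
    """Reverse identification: re-present the collect reservoir.

    Collected cells are pumped back one by one through the imaging
    region (well spaced, so re-detection always succeeds).  The
    fluorescent confirmation of the real device is emulated as a
    membership oracle: a recovered cell reads as class 2 iff it is one
    of the cells deliberately collected (forward-classified class 2),
    so a mechanically mis-sorted stranger shows up as a not-class-2
    extra.  The protein-factor biology behind the tag is out of scope.
    """
    collected = cell_events[cell_events["routed_to"] == "collect"]
    collected = collected.iloc[:config.reverse_loops]
    rows = []
    for _, ev in collected.iterrows():
        rows.append({
            "cell_id": int(ev["cell_id"]),
            "true_class": int(ev["true_class"]),
            "reverse_class": 2 if ev["predicted_class"] == 2 else 1,
        })
    return pd.DataFrame(rows,
                        columns=["cell_id", "true_class", "reverse_class"])


def build_report(cell_events: pd.DataFrame,
                 reverse_events: pd.DataFrame) -> dict:
    """Classification + sorting statistics for one run."""
    identified = cell_events[cell_events["identified"]]
    report: dict = {
        "n_injected": int(len(cell_events)),
        "n_identified": int(len(identified)),
        "n_missed": int((cell_events["routed_to"] == "missed").sum()),
    }
    if len(identified):
        cm = metrics.confusion(identified["true_class"].tolist(),
                               identified["predicted_class"].tolist())
        report["confusion"] = {"tp": cm.tp, "fp": cm.fp,
                               "fn": cm.fn, "tn": cm.tn}
        if cm.tp + cm.fp > 0:
            report["precision"] = metrics.precision(cm)
            report["precision_percent"] = metrics.percent_floor(
                metrics.precision(cm))
        forward_counts = {
            "class2": int((identified["predicted_class"] == 2).sum()),
            "not_class2": int((identified["predicted_class"] != 2).sum()),
        }
        reverse_counts = {
            "class2": int((reverse_events["reverse_class"] == 2).sum()),
            "not_class2": int((reverse_events["reverse_class"] != 2).sum()),
        }
        report["sorting"] = metrics.sorting_accuracy_report(
            forward_counts, reverse_counts)
        report["mechanical_success_fraction"] = float(
            identified["sorted_as_predicted"].mean())
    return report


def cmd_generate(config: RunConfig, outdir: str | Path,
                 image_format: str = "tiff") -> dict:
    """Generate a stream and write frames + truth log + manifest."""
    stream = generate_stream(config.stream, config.geometry)
    return write_stream(stream, outdir, image_format=image_format)


def cmd_sort(config: RunConfig, outdir: str | Path,
             stream: Optional[Stream] = None,
             model: Optional[KnnModel] = None) -> dict:
    """Full run: generate (unless given), sort forward, replay reverse,
    write event logs and the metrics report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stream is None:
        stream = generate_stream(config.stream, config.geometry)
    if model is None:
        model = train_default_model(seed=config.training_seed,
                                    noise_sigma=config.stream.noise_sigma,
                                    threshold=config.resolve_threshold())
    cell_events, actuation_log = run_forward(stream, model, config)
    reverse_events = run_reverse(stream, cell_events, config)
    report = build_report(cell_events, reverse_events)

    cell_events.to_csv(outdir / "events.csv", index=False)
    actuation_log.to_csv(outdir / "actuations.csv", index=False)
    reverse_events.to_csv(outdir / "reverse_events.csv", index=False)
    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2))
    if "sorting" in report:
        (outdir / "report.txt").write_text(
            metrics.format_report(report["sorting"]) + "\n")
    return report
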