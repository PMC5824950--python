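"""Discrete-event transport simulation from ROI to sorting junction.

The simulator consumes truth-level cell events (entry time, velocity,
size, class) rather than rendered frames, so questions of sorting
fidelity versus spacing and velocity decouple from image quality.

Model.  The sorting loop ticks at the timing model's average loop
delay for the configured camera ROI; a frame in which a new cell is
found costs the worst-case delay instead (full classification).  A
cell is identified iff it is fully inside the detection window at some
tick and no other cell is being processed at that tick; when several
unidentified cells are present the most upstream (most recently
entered) one wins, exactly as the upstream-first scan does.  The valve
switch commanded by a classification completes after the worst-case
loop plus a random mechanical latency, and a cell is routed by
whatever valve state holds when it crosses the junction — so a switch
triggered by a trailing cell can mis-route a leading cell that is
still in transit, which is the miss-sorting mode observed with
closely spaced particles.

Note on the loop delay: the bead-sorting experiments ran at a nearly
constant frame rate regardless of detection-window size, so the
simulator keeps the camera ROI (which sets the loop delay) and the
detection-window length as independent parameters, defaulting to the
design pairing of a 600 × 170 px ROI watching a 220 μm window.

Velocities are constant per cell (plug-flow approximation).  Units:
lengths μm, times ms, concentrations cells/mL.
"""

from __future__ import annotations

import math
import statistics
from bisect import bisect_right
from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .controller import COLLECT, Route, WASTE, route_for_class
from .geometry import ChannelGeometry, DEFAULT_GEOMETRY
from .timing import DEFAULT_TIMING, TimingParams, loop_delays

#: Camera ROI (px) whose loop delay drives the frame clock by default.
DEFAULT_CAMERA_ROI_PX = (600, 170)

#: Upper bound of the uniform mechanical valve-switch latency.  The
#: fastest cell covers the 500 μm detection-to-junction headroom in
#: 250 ms; with the 94 ms worst-case loop this bound keeps switching
#: within the budget for every isolated cell, matching the observation
#: that well-spaced cells always sorted correctly.
DEFAULT_LATENCY_MAX_MS = 150.0

UM3_PER_ML = 1e12


def cross_section_area(width_um: float, height_um: float) -> float:
    """Cross-section of the semicircular-profile channel, μm²:
    A = (2/3)·w·h."""
    if width_um <= 0 or height_um <= 0:
        raise ValueError("width and height must be positive")
    return (2.0 / 3.0) * width_um * height_um


def max_concentration(area_um2: float, d_min_um: float) -> float:
    """Maximum sortable cell concentration, cells/mL.

    One cell per ``area × d_min`` of channel volume:
    C = 1 / (A·d_min), converted from μm⁻³ to mL⁻¹.
    """
    if area_um2 <= 0 or d_min_um <= 0:
        raise ValueError("area and d_min must be positive")
    return UM3_PER_ML / (area_um2 * d_min_um)


def recommended_inlet_concentration(limit_cells_per_ml: float,
                                    margin: float = 4.0) -> float:
    """Inlet concentration compensating sheath-flow dilution and
    reservoir losses; at least a 3× margin, defaulting to 4× which
    lands on a round 1 × 10⁷ cells/mL for the stock geometry."""
    if margin < 1:
        raise ValueError("margin must be >= 1")
    return margin * limit_cells_per_ml


def transit_time_ms(length_um: float, velocity_um_s: float) -> float:
    """Time to cover ``length_um`` at ``velocity_um_s``, in ms."""
    if velocity_um_s <= 0:
        raise ValueError("velocity must be positive")
    if length_um < 0:
        raise ValueError("length must be >= 0")
    return 1000.0 * length_um / velocity_um_s


@dataclass(frozen=True)
class TransportCell:
    """Truth-level description of one cell entering the ROI."""

    cell_id: int
    t_enter_ms: float           # centre crosses the window's upstream edge
    velocity_um_s: float
    diameter_um: float
    true_class: int

    def window(self, roi_length_um: float) -> Tuple[float, float]:
        """Interval during which the cell is fully inside the window."""
        v = self.velocity_um_s
        t_in = self.t_enter_ms + transit_time_ms(self.diameter_um / 2.0, v)
        t_out = self.t_enter_ms + transit_time_ms(
            roi_length_um - self.diameter_um / 2.0, v)
        return t_in, t_out


@dataclass
class SortOutcome:
    """Per-cell event log and its summary counts."""

    events: pd.DataFrame

    @property
    def n_injected(self) -> int:
        return len(self.events)

    @property
    def n_identified(self) -> int:
        return int(self.events["identified"].sum())

    @property
    def n_correctly_routed(self) -> int:
        return int(self.events["correct"].sum())

    @property
    def identification_fraction(self) -> float:
        return self.n_identified / self.n_injected if self.n_injected else 0.0

    @property
    def all_routed_correctly(self) -> bool:
        return self.n_correctly_routed == self.n_injected

    def conservation_ok(self) -> bool:
        """Every injected cell ends in exactly one of
        collect/waste/missed."""
        routed = self.events["routed_to"]
        return bool(routed.isin(["collect", "waste", "missed"]).all()
                    and len(routed) == self.n_injected)


def _route_name(route: Route) -> str:
    return "collect" if route == COLLECT else "waste"


def simulate_sorting(cells: Sequence[TransportCell],
                     geometry: ChannelGeometry = DEFAULT_GEOMETRY,
                     timing: TimingParams = DEFAULT_TIMING,
                     camera_roi_px: Tuple[int, int] = DEFAULT_CAMERA_ROI_PX,
                     latency_max_ms: float = DEFAULT_LATENCY_MAX_MS,
                     seed: int = 0,
                     classify: Optional[Callable[[TransportCell], int]] = None,
                     ) -> SortOutcome:
    """Replay the sorting loop over a cell stream.

    ``classify`` maps a cell to its predicted class (defaults to the
    true class, i.e. a perfect classifier, which isolates transport
    effects).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    worst_ms, avg_ms = loop_delays(camera_roi_px[0] * camera_roi_px[1],
                                   timing)
    roi_len = geometry.roi_length_um
    cells = sorted(cells, key=lambda c: (c.t_enter_ms, c.cell_id))
    windows = {c.cell_id: c.window(roi_len) for c in cells}

    t = 0.0
    next_idx = 0                      # first cell not yet activated
    active: List[TransportCell] = []  # entered, not yet identified/expired
    identified_at: dict[int, float] = {}
    predicted: dict[int, int] = {}
    # Valve timeline: switch completion times and resulting routes.
    # Valves follow the waste routing until the first classification.
    switch_times: List[float] = [-math.inf]
    switch_routes: List[Route] = [WASTE]
    last_class: Optional[int] = None

    end_time = max((windows[c.cell_id][1] for c in cells), default=0.0)
    while t <= end_time + avg_ms:
        while next_idx < len(cells) \
                and windows[cells[next_idx].cell_id][0] <= t:
            active.append(cells[next_idx])
            next_idx += 1
        active = [c for c in active if windows[c.cell_id][1] > t
                  and c.cell_id not in identified_at]
        present = [c for c in active if windows[c.cell_id][0] <= t]
        if present:
            # Upstream-first scan: the most recently entered cell wins.
            cell = max(present, key=lambda c: (c.t_enter_ms, c.cell_id))
            identified_at[cell.cell_id] = t
            pred = classify(cell) if classify is not None \
                else cell.true_class
            predicted[cell.cell_id] = pred
            if last_class is None or pred != last_class:
                latency = rng.uniform(0.0, latency_max_ms) \
                    if latency_max_ms > 0 else 0.0
                switch_times.append(t + worst_ms + latency)
                switch_routes.append(route_for_class(pred))
            last_class = pred
            t += worst_ms           # classification blocks the loop
        else:
            if next_idx < len(cells) and not active:
                # Fast-forward along the tick grid to the next arrival.
                target = windows[cells[next_idx].cell_id][0]
                skip = max(0, math.floor((target - t) / avg_ms))
                t += skip * avg_ms
            t += avg_ms

    # Apply switches in completion order; a later completion overrides.
    order = np.argsort(switch_times, kind="stable")
    times_sorted = [switch_times[i] for i in order]
    routes_sorted = [switch_routes[i] for i in order]

    rows = []
    for c in cells:
        ident = c.cell_id in identified_at
        t_det = identified_at.get(c.cell_id, math.nan)
        if ident:
            t_junction = t_det + transit_time_ms(
                geometry.roi_to_junction_um, c.velocity_um_s)
            route = routes_sorted[bisect_right(times_sorted, t_junction) - 1]
            routed_to = _route_name(route)
        else:
            t_junction = math.nan
            routed_to = "missed"
        target = _route_name(route_for_class(c.true_class))
        rows.append({
            "cell_id": c.cell_id,
            "t_enter_ms": c.t_enter_ms,
            "velocity_um_s": c.velocity_um_s,
            "diameter_um": c.diameter_um,
            "true_class": c.true_class,
            "predicted_class": predicted.get(c.cell_id, 0),
            "identified": ident,
            "t_detected_ms": t_det,
            "t_junction_ms": t_junction,
            "routed_to": routed_to,
            "correct": routed_to == target,
        })
    return SortOutcome(events=pd.DataFrame(rows))


def spaced_stream(n_cells: int, spacing_frames: float,
                  frame_ms: float,
                  rng: np.random.Generator,
                  velocity_range: Tuple[float, float] = (600.0, 2000.0),
                  diameter_range: Tuple[float, float] = (5.0, 10.0),
                  classes: str = "random") -> List[TransportCell]:
    """Build a regularly spaced cell stream for fidelity experiments.

    ``classes='alternating'`` mimics the bead experiment (every other
    particle routed oppositely, so every cell demands a valve switch);
    ``'random'`` draws the three morphology classes uniformly.
    """
    cells = []
    for i in range(n_cells):
        if classes == "alternating":
            cls = 2 if i % 2 == 0 else 1
        elif classes == "random":
            cls = int(rng.integers(1, 4))
        else:
            raise ValueError("classes must be 'random' or 'alternating'")
        cells.append(TransportCell(
            cell_id=i,
            t_enter_ms=i * spacing_frames * frame_ms,
            velocity_um_s=float(rng.uniform(*velocity_range)),
            diameter_um=float(rng.uniform(*diameter_range)),
            true_class=cls,
        ))
    return cells


def identification_experiment(roi_length_um: float,
                              n_cells: int = 1500,
                              spacing_frames: float = 15.0,
                              seed: int = 0,
                              geometry: ChannelGeometry = DEFAULT_GEOMETRY,
                              timing: TimingParams = DEFAULT_TIMING,
                              camera_roi_px: Tuple[int, int] =
                              DEFAULT_CAMERA_ROI_PX) -> SortOutcome:
    """Identification fraction for well-spaced cells at uniform
    600–2000 μm/s velocities and a given detection-window length."""
    rng = np.random.default_rng(seed)
    _, avg_ms = loop_delays(camera_roi_px[0] * camera_roi_px[1], timing)
    cells = spaced_stream(n_cells, spacing_frames, avg_ms, rng)
    geom = ChannelGeometry(
        width_um=geometry.width_um, height_um=geometry.height_um,
        roi_length_um=roi_length_um,
        roi_to_junction_um=geometry.roi_to_junction_um,
        min_spacing_um=geometry.min_spacing_um)
    return simulate_sorting(cells, geom, timing, camera_roi_px, seed=seed)


def min_spacing_for_sorting(spacings: Iterable[int] = range(1, 16),
                            n_cells: int = 32,
                            replicates: int = 3,
                            seed: int = 0,
                            geometry: ChannelGeometry = DEFAULT_GEOMETRY,
                            timing: TimingParams = DEFAULT_TIMING,
                            camera_roi_px: Tuple[int, int] =
                            DEFAULT_CAMERA_ROI_PX,
                            latency_max_ms: float = DEFAULT_LATENCY_MAX_MS,
                            ) -> int:
    """Smallest inter-cell spacing (frames) at which every cell routes
    correctly.

    Uses alternating routes (the bead protocol: every cell forces a
    valve switch, the worst case) and small beads.  The threshold of a
    single sweep is an extreme statistic, so the sweep is replicated
    with independent seeds and the median reported.
    """
    spacings = sorted(spacings)
    _, avg_ms = loop_delays(camera_roi_px[0] * camera_roi_px[1], timing)
    results = []
    for r in range(replicates):
        found = spacings[-1] + 1
        for s in spacings:
            rng = np.random.default_rng(seed + 1000 * r + s)
            cells = spaced_stream(n_cells, float(s), avg_ms, rng,
                                  diameter_range=(4.5, 5.5),
                                  classes="alternating")
            outcome = simulate_sorting(
                cells, geometry, timing, camera_roi_px,
                latency_max_ms=latency_max_ms, seed=seed + 1000 * r + s)
            if outcome.all_routed_correctly:
                found = s
                break
        results.append(found)
    return int(statistics.median(results))
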