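"""Valve and pump control logic.

The chip is driven by three-valve peristaltic pumps cycling through the
pattern 110-011-001-101 (0 = valve open, 1 = valve closed, following
the hardware convention verbatim to avoid sign bugs).  Pump speed is
reduced by inserting idle "cycle delays" between pattern cycles: d
delays give 1/(1+d) of full speed.  Sorting is done by two valves at a
Y junction; the controller switches them only when consecutive cells
are classified differently, which minimizes valve wear and switching
transients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional, Tuple

#: Peristaltic switching sequence; 0 = open, 1 = closed.
PUMP_SEQUENCE: Tuple[Tuple[int, int, int], ...] = (
    (1, 1, 0),
    (0, 1, 1),
    (0, 0, 1),
    (1, 0, 1),
)

VALVE_OPEN = 0
VALVE_CLOSED = 1


class Route(NamedTuple):
    """Sorting-valve pair state; 0 = open, 1 = closed."""

    valve1: int
    valve2: int


#: Class-2 cells: valve 1 closed, valve 2 open -> collect channel.
COLLECT = Route(VALVE_CLOSED, VALVE_OPEN)
#: Everything else: valve 1 open, valve 2 closed -> waste channel.
WASTE = Route(VALVE_OPEN, VALVE_CLOSED)


def pump_pattern(step: int) -> Tuple[int, int, int]:
    """Valve triple at pump step ``step`` (periodic with period 4)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return PUMP_SEQUENCE[step % len(PUMP_SEQUENCE)]


def effective_speed(cycle_delay: int) -> float:
    """Fraction of full pumping speed with ``cycle_delay`` idle cycles
    between pattern cycles (1 delay -> 1/2, 3 -> 1/4, 7 -> 1/8)."""
    if cycle_delay < 0:
        raise ValueError("cycle_delay must be >= 0")
    return 1.0 / (1.0 + cycle_delay)


@dataclass(frozen=True)
class PumpProgram:
    """A pump's operating point: pattern period and speed divider."""

    pumping_period_ms: float = 50.0
    cycle_delay: int = 0

    def __post_init__(self) -> None:
        if not 10.0 <= self.pumping_period_ms <= 500.0:
            raise ValueError("pumping_period_ms must be within [10, 500]")
        if self.cycle_delay < 0:
            raise ValueError("cycle_delay must be >= 0")

    def pattern_at(self, slot: int) -> Tuple[int, int, int]:
        """Pattern emitted during base-period slot ``slot``.

        A full pattern cycle (4 slots) is followed by ``cycle_delay``
        idle cycles during which the last pattern is held, so the
        sequence advances 1/(1+cycle_delay) patterns per slot on
        average.
        """
        if slot < 0:
            raise ValueError("slot must be >= 0")
        cycle_len = 4 * (1 + self.cycle_delay)
        pos = slot % cycle_len
        return PUMP_SEQUENCE[min(pos, 3)]


@dataclass(frozen=True)
class SorterState:
    """Mode, valve map and sorting memory of the controller.

    Until the first cell is classified both sorting valves follow the
    waste routing, so unidentified fluid drains to waste.
    """

    mode: str = "idle"  # idle | forward | reverse
    valve1: int = VALVE_OPEN
    valve2: int = VALVE_CLOSED
    reverse_waste_valve: int = VALVE_CLOSED
    forward_pumps_on: bool = False
    reverse_pumps_on: bool = False
    last_class: Optional[int] = None


def set_mode(state: SorterState, mode: str) -> SorterState:
    """Switch between forward sorting, reverse identification and idle.

    Forward: the three sample/focusing pumps run, reverse path sealed.
    Reverse: forward pumps sealed, the two reverse pumps run and the
    reverse waste valve opens so collected cells stream back through
    the imaging region.  Idle: every pump stops and seals its channel
    to prevent pressure-driven flow.
    """
    if mode == "forward":
        return replace(state, mode=mode, forward_pumps_on=True,
                       reverse_pumps_on=False,
                       reverse_waste_valve=VALVE_CLOSED)
    if mode == "reverse":
        return replace(state, mode=mode, forward_pumps_on=False,
                       reverse_pumps_on=True,
                       reverse_waste_valve=VALVE_OPEN)
    if mode == "idle":
        return replace(state, mode=mode, forward_pumps_on=False,
                       reverse_pumps_on=False,
                       reverse_waste_valve=VALVE_CLOSED)
    raise ValueError(f"unknown mode: {mode!r}")


def route_for_class(cell_class: int) -> Route:
    """Valve pair for a classified cell: class 2 -> collect, else waste."""
    if cell_class not in (1, 2, 3):
        raise ValueError(f"invalid class: {cell_class!r}")
    return COLLECT if cell_class == 2 else WASTE


def on_cell_classified(state: SorterState,
                       cell_class: int) -> Tuple[SorterState, bool]:
    """Update the controller after a classification.

    The valves are actuated only when the class differs from the
    previous cell's (or no cell has been seen yet); identical
    consecutive classes leave the valves untouched.  Returns the new
    state and whether an actuation was issued.
    """
    actuate = state.last_class is None or cell_class != state.last_class
    route = route_for_class(cell_class)
    new = replace(state, valve1=route.valve1, valve2=route.valve2,
                  last_class=cell_class)
    return new, actuate


class CellTracker:
    """Assign cell identity to scan hits across consecutive frames.

    At the operating velocities a cell advances far more than its own
    diameter between frames, so identity cannot be decided by hit
    proximity.  Flow ordering decides instead: the scan always returns
    the most upstream cell, and cells only ever move downstream, so a
    hit is a *new* cell exactly when it lies upstream of the previous
    frame's hit (or when the previous frame was empty).
    """

    def __init__(self, upstream: str = "left") -> None:
        if upstream not in ("left", "right"):
            raise ValueError("upstream must be 'left' or 'right'")
        self._upstream = upstream
        self._last_x: Optional[int] = None

    def observe(self, found: bool, hit_x: Optional[int] = None) -> bool:
        """Feed one frame's scan result; True when the hit is a new cell."""
        if not found:
            self._last_x = None
            return False
        if hit_x is None:
            raise ValueError("hit_x required when found")
        if self._last_x is None:
            is_new = True
        elif self._upstream == "left":
            is_new = hit_x < self._last_x
        else:
            is_new = hit_x > self._last_x
        self._last_x = hit_x
        return is_new
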