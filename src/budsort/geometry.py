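"""Microchannel geometry shared by the imaging and transport modules.

The device is a two-layer PDMS chip: a 60 μm wide, 20 μm high fluidic
channel with a Y-shaped sorting junction downstream of the imaging
region.  The region of interest (ROI) the detector watches is placed
500 μm upstream of the junction so that classification and valve
switching can complete while the cell is still in transit.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChannelGeometry:
    """Channel and sorting-layout dimensions, all in micrometres.

    Parameters
    ----------
    width_um, height_um
        Fluidic channel cross-section (60 × 20 μm by default).  The low
        ceiling confines 5–10 μm yeast cells near the channel mid-plane.
    roi_length_um
        Length of the detection window along the flow axis.
    roi_to_junction_um
        Headroom between where a cell is detected and the sorting
        junction; the valve-switching budget is the time to cover it.
    min_spacing_um
        Minimum inter-cell spacing assumed by the concentration limit.
    """

    width_um: float = 60.0
    height_um: float = 20.0
    roi_length_um: float = 220.0
    roi_to_junction_um: float = 500.0
    min_spacing_um: float = 500.0

    def __post_init__(self) -> None:
        for name in ("width_um", "height_um", "roi_length_um",
                     "roi_to_junction_um", "min_spacing_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_GEOMETRY = ChannelGeometry()
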