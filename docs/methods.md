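# Methods

`budsort` is a software twin of an image-based microfluidic yeast cell
sorter. This note records the models behind each module, the
parameters that matter, the choices made where the design was open,
and what the synthetic experiments do and do not demonstrate.

## Synthetic imaging model

Cells are rendered as dark two-disk figures on a light background:
a mother disk (radius 2.5–5.0 μm, i.e. 5–10 μm cell diameter) and,
for budded cells, a bud disk placed at a random angle with centre
distance `r_m + 0.6·r_b`, so the disks overlap and form a neck. The
figure is blurred with a 1 px Gaussian to emulate a soft optical edge.
Intensities are fixed on an 8-bit scale: background 200, cell
interior 80 counts darker, fluorescent beads 55 counts brighter;
zero-mean Gaussian sensor noise (default σ = 3) is added per frame.
The default pixel pitch is 0.562 μm/px (a 1600 px sensor spanning a
~900 μm field).

Class-conditional bud ratios are drawn uniformly: class 2 from
(0.15, 0.45), class 3 from (0.50, 0.90). The class-2 lower bound is a
morphological choice: below ~15 % of the mother radius a bud is a
sub-pixel bump at this pitch, i.e. a transitional cell that even a
human annotator could not separate from unbudded; the gap at
0.45–0.50 reflects that the class boundary is a convention, not a
physical discontinuity.

Streams place cells at the channel mid-height (sheath-flow focusing
is emulated as single-file centering with ±2 px residual offset) and
advance each cell by `velocity × frame interval` per frame; velocities
are uniform on 600–2000 μm/s, constant per cell (plug-flow
approximation). Arrival spacing is fixed or exponential, in frames.
One integer seed determines the stream bit-exactly.

What the generator does *not* emulate: brightfield texture and
diffraction rings, optical PSF, out-of-plane motion, cell rotation,
deformation, clumps, debris. Tests passing on this generator
demonstrate the correctness of the *pipeline logic* (detection
geometry, feature recovery, control and transport behaviour), not
classification performance on real micrographs.

## Detection

Frames are compared to a pre-run background image by absolute
difference, so static artifacts cancel and dark cells and bright
beads are handled uniformly. The scan visits every fifth column
(upstream first) and every fifth row and exits at the first pixel
above threshold. The default threshold is 5 × the noise σ (floored at
5 counts for noise-free synthetic streams), far above the noise floor
yet far below the half-contrast of any cell. Stride 5 is sound for
this population: the thresholded footprint of the smallest mother
(radius ≈ 4.4 px, slightly dilated by the rim blur) always contains a
point of the 5 px grid.

## Segmentation and features

The cell is the connected component of above-threshold difference
pixels containing the scan hit, holes filled. Because the detection
threshold sits low on the blurred rim, that component is dilated by
about one pixel; the mask is therefore refined at half the
component's peak difference — for a Gaussian-blurred step the
half-contrast contour is exactly the true boundary. A component
touching the image border is flagged truncated.

Features are `{area, mother radius, bud radius, bud ratio,
eccentricity}`. The mother radius is the largest inscribed disk
(Euclidean distance-transform maximum); pixels outside that disk form
the residual, whose largest connected blob is the bud if it reaches
3 px². With the generator's neck geometry the largest disk inscribed
in the residual has radius `0.8·r_b` (the bud centre lies `0.6·r_b`
outside the mother boundary and the bud tip `1.6·r_b`), so the
estimate is multiplied by 1.25; this estimator is deliberately matched
to the rendering model and is a stand-in for whatever feature set a
real system would use. The 3 px² minimum-bud area balances two error
rates: false buds require a noise excursion past the 5σ threshold
(negligible), while a real bud on a small mother leaves a residual of
only ~4 px², so a larger cutoff would silently erase legitimate
class-2 buds.

## Classification

A self-trained kNN with k = 3 on z-normalized features (location and
scale from the training set), Euclidean distance, 30 training samples
per class. Neighbours are ordered by (distance, training index) so
prediction is deterministic; a three-way tie is resolved to the single
nearest neighbour's class. Hold-out accuracy on clean synthetic cells
is 88–93 % depending on seed, against a reference of 80 %; residual
errors concentrate where they should — smallest buds on smallest
mothers, and ratios near the 0.5 class boundary.

## Controller

Valve states use the hardware convention 0 = open, 1 = closed. The
peristaltic sequence is 110-011-001-101; `d` idle cycles between
pattern cycles give `1/(1+d)` of full speed. Routing: class 2 closes
valve 1 and opens valve 2 (collect), everything else the reverse; the
valves are switched only when consecutive cells classify differently,
and both sorting valves follow the waste routing before the first
classification. Repeated detections of one cell across frames are
de-duplicated by flow ordering — a hit is a new cell iff it lies
upstream of the previous frame's hit or follows an empty frame —
because at 600–2000 μm/s a cell advances 60–130 μm between frames,
far more than its own diameter, so proximity-based identity cannot
work.

## Timing model

Loop delay = 33 ms acquisition + scan + classification. Scan time is
`ceil(ROI pixels / 4000)` ms; classification is a constant 35 ms,
amortized to 3.5 ms per loop at the nominal one-cell-per-10-frames
rate. Scan and average delays round *up* to whole ms and frame rates
truncate to one decimal; under these conventions the model reproduces
the published delay table exactly for the three smaller ROIs, while
the two largest ROIs (which were timed empirically rather than
derived) agree within 1 ms of scan time.

## Transport simulation

The simulator consumes truth-level events (entry time, velocity,
diameter, class), not frames, so fidelity questions decouple from
image quality. The loop ticks at the average delay of the configured
*camera* ROI (600 × 170 px → 63 ms by default); a frame that detects
a new cell costs the worst case (94 ms) instead. A cell is identified
iff it is *fully inside* the detection window at some tick — the
classifier needs the whole cell in view — and loses to a more
upstream cell present at the same tick. The camera ROI (pixels, sets
the loop delay) and the detection-window length (μm) are independent
parameters: the bead experiments ran at nearly constant frame rate
across window sizes, and coupling them through any single pixel pitch
would contradict that observation (the published px↔μm pairings
themselves imply two different pitches).

A classification issues a valve switch completing after the
worst-case loop plus a mechanical latency drawn uniformly from
[0, 150] ms. The bound is derived from the transit budget: a cell is
routed by the valve state when it crosses the junction, 500 μm
(250–833 ms) downstream of detection, and switching was observed to
always complete within that budget, which requires
94 + latency ≤ 250 ms. A switch triggered by a trailing cell can
therefore re-route a leading cell still in transit — the observed
miss-sorting mode for closely spaced particles.

`min_spacing_for_sorting` estimates the smallest arrival spacing with
zero routing errors, using alternating target/non-target cells (every
cell forces a switch, the worst case, mirroring the odd/even bead
protocol) with 32 cells per spacing. Because a single sweep's
threshold is an extreme statistic, the sweep is replicated three
times with independent seeds and the median reported; estimates land
at 10–12 frames, inside the bracket set by the observed 6 frames and
the 12-frame worst-case guarantee. The concentration limit
`C = 1/(A·d_min)` uses the semicircular-channel approximation
`A = (2/3)·w·h`; the recommended inlet concentration applies a 4×
margin (at least the 3× dilution/adhesion loss estimate, rounded to a
round number).

## End-to-end pipeline

The frames-in path composes detection, segmentation, classification
and control per frame at the generator's fixed frame cadence; valve
completion times add the full 35 ms classification plus latency, and
routing is resolved against each cell's truth trajectory as in the
transport model. The reverse pass re-presents the collect reservoir
well spaced, emulating fluorescent confirmation as a membership
oracle (a recovered cell reads as class 2 iff it was deliberately
collected), so the sorting-success statistic isolates *mechanical*
errors from classification errors — a stranger in the collect
reservoir or a lost collected cell counts as a mis-sort, and the
Wilson score interval (normal quantile from the inverse CDF, not a
rounded 1.96) summarizes the success proportion.

## Problem sizes and determinism

Default experiment sizes: classifier evaluation uses 30 training and
300 test cells per class; identification experiments use 1500 cells
at 15-frame spacing; spacing sweeps 32 cells × spacings 1–15 × 3
replicates; end-to-end demos use 10–15 cells. All randomness flows
from integer seeds through `numpy.random.default_rng`; equal
configurations produce byte-identical frames, logs and reports.

## Known limitations

* The two-disk appearance model and the matched bud estimator make
  classification accuracy on synthetic data an upper bound on
  real-data performance; only the pipeline logic transfers directly.
* Plug flow ignores the velocity dispersion and deceleration a real
  cell experiences between ROI and junction.
* The pneumatic side (membrane mechanics, pressure dynamics) is
  abstracted into the single latency bound.
* One detection per frame: two cells inside the window at the same
  tick shadow each other by design, as in the original loop.
* The fluorescent-protein biology of reverse mode is out of scope;
  reverse mode is routing plus re-detection only.
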