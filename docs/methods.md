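# Methods

This note documents the models, conventions, and design decisions behind
loopscope: a closed-loop optogenetic microscopy engine in which a master
scheduler sequences imaging, nuclear segmentation, stimulus-pattern
computation, and patterned illumination across multipoint positions, with
a simulated microscope standing in for the hardware.

## The closed loop

A validated experiment plan (master schedule + stage positions + one
module configuration per position) is expanded into a deterministic event
timeline: image events at every multiple of the imaging interval and
stimulate events at every multiple of the stimulation interval, both
including t = 0 and the final time. Each image event is followed, at the
same timestamp, by a segment event (when segmentation is configured) and
a compute-pattern event (when the position's pattern module is
closed-loop, i.e. consumes masks). Simultaneous events are ordered
stimulate < image < segment < compute-pattern, then by position order;
the single exception is t = 0 at closed-loop positions, where the
stimulate event runs last so the very first stimulation can already use a
mask instead of the dark fallback.

The ordering contract — the pattern projected at any stimulate event at
time t derives from the most recent completed segmentation whose source
frame time is at most t — is what downstream code may rely on, not any
particular threading mechanism. The reference executor is a
single-threaded event loop over a simulated clock, so the contract holds
by construction; `validate_record` nevertheless re-checks it by replaying
any run record, because a future real-time executor may overlap
computation with acquisition.

Failure semantics: any module exception is logged against its event and
the loop continues. Stimulation cadence is never broken — if no pattern
has been computed yet, or the pattern module failed, the most recent
valid pattern (or an all-dark frame) is projected. We chose all-dark
rather than all-bright as the primordial fallback so that a failing
closed-loop position never delivers unintended stimulation. Each
position's simulator state and random stream are keyed by the position
name, so a position's failure (or removal) leaves every other position's
record byte-identical.

## Stimulus patterns

All patterns are intensity maps in [0, 1] on the camera pixel grid.
Arrays are indexed [row, col]; physical x increases with column and y
with row (downward on screen), with the origin at the top-left pixel
center. "Counter-clockwise" always means counter-clockwise on screen,
which in this row-down frame makes the ccw tangent of an offset
(rx, ry) equal to (ry, −rx)/|r|.

**Traveling bars.** A row at physical y is lit iff
wrap(y − y0 − v·t, P) < d·P, with period P (µm), signed speed v (µm/h;
positive toward increasing y), duty d, and offset y0. Bars are binary;
the wave phase of a position is the signed offset to the nearest bar
*center* in cycles, in [−0.5, 0.5), positive ahead of the center in the
travel direction, so a pixel is lit exactly when its phase lies in
[−d/2, d/2).

**Voronoi vortex.** Nuclear centroids partition the FOV into Voronoi
territories (nearest centroid, Euclidean over pixel centers, exact ties
to the smaller label). Within each territory the intensity ramps
linearly along the ccw tangent of the cell's centroid about the FOV
center, normalized over the territory's own extent (a configuration
flag allows normalizing over the FOV instead), so each cell's brightest
territory edge faces its intended direction of motion. A cell exactly
at the rotation center receives uniform half power; a degenerate
single-pixel territory receives full power.

**Bang-bang feedback.** Each segmented cell's mean intensity on the
controlled channel is compared with its set point — a scalar, or a
grayscale set-point image averaged over the cell's mask pixels (mean
rather than centroid lookup, for noise robustness). Cells below
set point minus the hysteresis band (default 0: a plain thermostat) get
their whole mask region lit at full power; everything else is dark.

**Pattern manager.** Computed patterns are stored per position with
their validity times; the manager serves the stored pattern with the
greatest validity time not exceeding the request, evaluates open-loop
modules (bars, constant) directly at the requested time, and falls back
to all-dark before anything is available.

## The simulated microscope

The simulator makes the entire engine testable without hardware. Each
stage position owns an independent field of agent cells, a camera model,
and an illumination state.

**Cells.** Positions are scattered uniformly or on a jittered grid;
baseline fluorescences are lognormal with unit mean and configurable
coefficient of variation (default 0.45, emulating a variably expressed
nuclear marker); the nuclear radius defaults to 3 µm.

**Photochromism.** The fluorophore mimics a photochromic red protein
that brightens reversibly under blue light: two-state first-order
kinetics with fluorescence relaxing toward fold × baseline under
illumination (time constant tau_on = 30 s) and back toward baseline in
the dark (tau_off = 120 s), fold = 4.5. The update uses the exact
exponential solution, so fluorescence provably never leaves
[baseline, fold × baseline]. Only the fold change and reversibility are
literature-grounded; the time constants are model choices. Note that
full reversibility to within 1% of baseline takes ln(350·)/… ≈ 5.9
dark time constants at this dynamic range — reversibility checks run 8
tau_off.

**Motility.** Each cell carries a polarity vector p with velocity
v0·p (v0 = 10 µm/h) plus diffusive noise (1 µm/√h). Polarity relaxes
toward a drive computed from the illumination field L:

    Ls    = gaussian(L, sensing_sigma)           # spatial integration
    drive = unit(∇Ls) · min(alpha·|∇Ls|, 1) · gate

with sensing_sigma = 15 µm for supracellular stimuli and alpha = 60 µm.
The *adaptation gate* is the model's key asymmetry: the local intensity
rise rate is estimated against an exponential-memory field (time
constant 30 min), and positive rise rates are passed through a sharp
Hill function (half-rate 0.6 h⁻¹, exponent 8). Slowly brightening
surroundings — an approaching slow wave — therefore elicit no response,
while rapid brightening (a fast wave sweeping past) and any dimming or
static gradient elicit the full response. Drives below a response
threshold (0.1) are not sensed at all; polarity then persists, decaying
slowly (tau 180 min), whereas an active drive re-orients it with tau
20 min. Cells reflect at the FOV boundary (position folds back,
polarity flips); assays that emulate a window into a much larger tissue
can use periodic boundaries instead.

This is a phenomenological model. Its obligations are qualitative:
cells chase a receding slow bar (light loss behind the trailing edge is
an un-gated dimming signal, and chasing prolongs it), rock back and
forth under fast bars (brightening is then fast enough to beat the
gate, so incoming attraction appears), climb static gradients, and
aggregate toward constantly lit regions. With the default parameters a
speed sweep of {8, 12, 25, 50} µm/h bars yields mean tissue speeds of
roughly {4.7, 6.9, 3.1, 0.9} µm/h — a unimodal curve with an interior
optimum at 12 µm/h, all phase bins positive at 12 µm/h, and
sign-changing phase bins at 50 µm/h. No quantitative agreement with any
particular tissue is claimed, and the model omits cell division, death,
mechanics, and cell–cell coupling entirely — collective effects in real
epithelia will differ.

Two geometric constraints matter when designing wave assays on this
model: the inter-bar gap should exceed twice the sensing range (here:
period 160 µm at duty 0.5), otherwise cells midway between bars sense
both edges at once and are attracted to the approaching bar at any
speed; and the first few hours contain a stimulus-onset transient
(cells respond to the freshly appearing pattern before their adaptation
state exists) that analysis should discard — the reference protocol
runs 16 h and discards 4 h. For the subcellular Voronoi-gradient
stimulus the sensing scale must be the cell body itself
(sensing_sigma ≈ the 3–4 µm nuclear radius); blurring at the
supracellular scale averages adjacent territories' ramps away.

**Camera.** Each cell renders as an isotropic Gaussian spot with width
sqrt(psf² + radius²), constant amplitude in the nuclear channel and
amplitude proportional to current fluorescence in the fluorescence
channel, over a constant background (5 camera units) with Gaussian read
noise (sigma 2) and clipping at zero.

## Segmentation and measurement

The built-in segmenter is deterministic: Gaussian smoothing (sigma
2 px), Otsu threshold, 8-connected labeling, area filter, and
renumbering 1..n in raster order of first pixel. It is the segmenter
used throughout testing; a learned external segmenter can be swapped in
per position through the adapter, which resolves (and fails) at
plan-build time so a missing backend never surfaces mid-run. Per-cell
measurements are intensity-unweighted centroids in (x, y) = (col, row)
pixel units, areas, and per-channel mean intensities. On well-separated
synthetic fixtures (grid spacing ≥ 6 effective spot sigmas, SNR ≈ 75)
the segmenter recovers exact counts with sub-pixel centroid error;
crowded fields will merge nuclei and need the external adapter.

## Analysis

Tracking links per-frame centroid lists by mutual nearest neighbours
within a gate (default 10 µm per frame), in ascending-distance order;
unmatched detections start new tracks. The live loop itself is
stateless across frames — tracking is a post-hoc analysis. Velocities
are central differences (one-sided at track ends) in µm/h. Wave-phase
binning partitions [−0.5, 0.5) cycles (default 20 bins) and reports the
per-bin mean ± SD of the velocity component signed along the wave's
travel direction; empty bins are reported as missing, never as zero,
and replicate-level aggregation (mean ± SD across position-level means)
is supported. Polar decomposition about a center yields v_radial
(positive outward) and v_tangential (positive ccw on screen, matching
the vortex pattern's chirality convention) with |v|² preserved; radial
profiles average v_tangential and angular velocity over equal-width
rings. The CV time course is SD/mean of per-cell mean intensities per
frame, scale-invariant by construction, with the fold reduction
CV(0)/CV(t) attached.

## Bang-bang control performance: the actuation-quantum limit

With the default kinetics, one control period (30 s) of full
illumination moves a cell 1 − e⁻¹ ≈ 63% of the way from its current
fluorescence to 4.5 × baseline, and one dark period removes ≈ 22% of
its elevation. A thermostat controller sampled this coarsely cannot
hold a tight band: each cell settles into a limit cycle whose amplitude
grows with its dynamic range (brighter-baseline cells overshoot more),
and the population CV saturates near 0.25 regardless of set point. The
reference control protocol (1000 cells, CV 0.45, set point 2.5× the
mean baseline, 40 steps) therefore achieves a CV fold reduction of
about 1.3–1.5, and a two-level set-point image brings roughly 90% of
cells into a ±10% band at some point within 40 steps. Tight control at
a 30 s cadence requires actuation that is slow relative to the control
period (tau_on of several minutes and slow dark decay): with, e.g.,
tau_on = 300 s and tau_off = 1800 s the same controller reaches a
fold reduction above 4. The per-cell dose–baseline relationship is
robust to all of this: cumulative light dose anti-correlates strongly
with baseline brightness (Spearman ≈ −0.98), i.e. the controller stores
the population heterogeneity in its inputs.

## Problem sizes

The reference protocols are scaled to run on one CPU in seconds to a
couple of minutes each: wave sweeps use 300 cells in a 96 × 768 µm
strip for 16 simulated hours per speed; the control runs use 1000 cells
on a jittered grid in 640 × 640 µm (so the threshold segmenter resolves
every nucleus) for 20 simulated minutes; the multipoint contract run
uses 15 positions of 40 cells for 10 simulated minutes; segmentation
recovery uses 100 independent 256 × 256 px fixtures of 30 nuclei.

## Known limitations

- No cell division, death, mechanics, or neighbour coupling; the
  motility model is phenomenological and calibrated only to qualitative
  wave/gradient behaviors.
- Illumination is binary for photochromic switching (any positive
  intensity counts as lit); graded dose–response is not modeled, and
  irradiance is not physically calibrated.
- The threshold segmenter assumes well-separated nuclei; dense fields
  need an external learned segmenter through the adapter.
- The live loop does not track cells across frames (tracking is
  post-hoc), so history-dependent controllers (e.g. integral feedback)
  are out of scope.
- Hardware execution is specified only as an interface contract; no
  hardware adapter ships in this build.
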