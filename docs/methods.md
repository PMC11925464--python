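# Methods

This note documents the models, conventions, defaults and limitations of
`valveflow`, and the design decisions taken where the underlying assays
left the choice open.

## Conventions

- Coordinates are 0-based `(row, col)` pixels; the heart tube runs
  posterior → anterior along increasing column index. All ROIs are
  half-open rectangles.
- Frame `k` of a recording is at time `k / frame_rate`; intensities are
  8-bit `[0, 255]`.
- Calibration (`pixel_size` in µm/px, `frame_interval` in s) is always an
  explicit input: the assays' recordings come from different optics with
  no standard magnification, so no default could be meaningful.
- RGB inputs are converted to luminance with ITU-R 601 weights
  (0.299, 0.587, 0.114); 8-bit conversion rescales the *global* min–max of
  a stack (per-frame scaling would distort slow accumulation trends).

## Synthetic scenes (`videogen`)

The generators render the study conditions of each assay with the true
parameters recorded, so downstream analyses are validated by parameter
recovery rather than by comparison with unavailable recordings.

**Heart-tube scene.** Dye angiography recordings run 30 s at ~100 fps.
Hemolymph moves as one discrete packet per heartbeat (2 beats/s by
default): each beat outside an arrest interval emits a Gaussian packet
(σ = 3 px) at the valve column, advected anteriorly at `packet_velocity`
(default 5.2 mm/s, the healthy-animal condition). Packet amplitude scales
linearly with `valve_opening_fraction` — a narrow opening passes less dye
per beat — and packets reaching the anterior margin deposit into a static
accumulation zone. The per-packet deposit (3.0 intensity units ×
opening fraction) is sized so a full 30 s control recording stays below
8-bit saturation; clipping would destroy the linear dose response the
accumulation index measures. The valve occluder is two opposing lobes
whose gap follows a raised cosine between closed and
`valve_opening_fraction × tube_width` (no waveform is prescribed by the
assay; the raised cosine is the smoothest periodic choice).
`valve_rest_gap_fraction > 0` emulates valves unable to seal the lumen
(the severe *rab5*-like phenotype). Camera noise is additive Gaussian
(default σ = 5), clipped to `[0, 255]`; cuticle darkening is a global
linear intensity drift (default 0.5 /s). Identical parameters and seed
give bit-identical output.

**Valve-label scene.** The same gap waveform rendered as two bright lobes
on black, the input of the kinematics analysis. The rendered gap is
quantised to whole pixel rows, with lobes extending 4 rows beyond the
lumen so a fully open valve still shows two components; touching lobes
represent the closed state.

**Particle scene.** Two channels at 200 fps: Gaussian particle spots
(σ = 1.5 px) and a static valve-region label emulating the cardiomyocyte
reporter signal. The lumen narrows near the valve by a Gaussian profile
(σ = 8 px) from `tube_width` down to `valve_opening_fraction ×
tube_width`; particle speed obeys kinematic continuity,
`v(col) · gap(col) = const`, integrated with 4 Euler substeps per frame.
Recorded per-point truth speeds are exact; `position_noise_px` jitters
only the rendered spots. Particles occupy distinct non-crossing lanes;
the collision-free capacity (rows spaced ≥ 4 spot σ) is enforced with an
explicit error.

**Crawl scene.** A larva silhouette as a capsule (default 3 mm × 0.6 mm)
of two spine segments meeting at a scheduled bend angle, centred — after
an internal recentring pass — on a waypoint path, with the heading
following the local tangent. The recorded centroid truth is accurate to
rasterisation error (< 0.5 px). A silhouette touching the frame border
raises, mirroring the discard rule for larvae leaving the arena.

**Fiber texture.** Sinusoidal stripes (wavelength 8 px) at a known
orientation mixed with uniform white noise in proportion `coherence`.

**What the scenes do not model:** optics (no PSF, no 3-D projection),
hemodynamic pressure (only kinematic continuity), retrograde flow,
peristalsis of the tube walls, particle–wall interactions, and the
heterogeneous anatomy visible in real recordings. Passing recovery tests
therefore demonstrates correctness of the measurement pipeline, not
robustness to every artefact of live imaging.

## Analysis choices

**Background subtraction** subtracts frame 0 and clips negatives to zero:
the ink tracer can only darken the animal, so negative differences are
noise.

**Accumulation index** is the mean trace value over a configurable
terminal window, default the final 1 s of the recording — robust to
single-frame noise while reflecting the 30 s endpoint.

**Cycle detection** uses prominence-based peak finding
(default prominence 10 intensity units). The baseline is the 0.1 quantile
of each trace — background level varies per animal with cuticle
darkening, so it is always estimated per recording. A cycle "closes ok"
if the trace falls back within 25 % of its peak-to-baseline excursion
before the next peak. Arrests are inter-peak gaps exceeding 2× the median
cycle period; an arrest interval starts at `last_peak + median_period`
(when the first expected beat was missed) and ends at the next observed
peak. The naive peak-to-peak interval over-covers a true arrest by up to
one period on each side and cannot reach the 0.8 Jaccard recovery this
convention achieves.

**Velocity estimation** matches posterior and anterior peaks
order-preservingly (earliest unused anterior peak within one median
cycle period). This generalises single-bulk timing to several cycles
(default 3). The method is only defined while at most one packet is
between the ROIs (transit time < beat period); the scenes used for
validation satisfy this by construction. A reversal check requires the
first threshold crossing to occur posteriorly first — peak matching alone
cannot see a reversed flow, it would silently match the next cycle.
Sub-frame peak interpolation (parabolic) exists but is off by default:
the native temporal resolution is one frame.

**Packet segmentation** is an 8-connected flood fill (the legacy
wand-tool behaviour; 4-connectivity switchable). Seeds whose flood covers
less than 4 px or more than half the frame (a background flood) are
flagged and excluded from the per-animal summary.

**Valve gap** is measured between the two thresholded label components:
minimum boundary-pixel separation restricted to directions within ±5° of
the perpendicular to the tube axis (tolerance absorbs mask pixelation),
minus one pixel of boundary-to-boundary allowance so adjacent pixels give
gap 0. One merged component is the closed state (gap 0); zero or > 2
components flag the frame invalid — isolated invalid frames are
interpolated, longer runs raise. "Closed" needs a numeric criterion: gap
≤ `closure_threshold`, with one pixel-equivalent as the sensible default.
An opening event runs from the first open frame after one closure to the
first open frame after the next — the time from initial luminal opening
until the end of the following closure, i.e. one close-to-close cycle.
Peak opening distance is measured by peak detection on the gap signal
itself, so it remains defined for valves that never close; those return
an explicit `cannot_estimate_never_closed` status instead of a number.

**Tracking** replaces manual particle clicking with
Laplacian-of-Gaussian detection (sub-pixel quadratic refinement) and
greedy mutual-nearest-neighbour frame-to-frame linking (chosen for
transparency; the exhaustive optimal assignment serves as the test
oracle). Links beyond `max_disp` px/frame are forbidden; gaps up to
`max_gap` frames are bridged with proportionally scaled limits. A step's
speed is assigned to its midpoint for region gating. The confinement
ratio of a zero-length path is 1 by convention.

**Directionality** follows the Fourier-components convention: 90 bins of
2° over [−90°, 90°), each non-DC spectral sample binned at its frequency
vector's angle + 90° (structure at θ concentrates power along θ + 90°),
power-normalised. Dispersion is the axial (180°-periodic) circular
standard deviation. Fiber orientation is axial, hence the folding.

**Fiber density** is the above-threshold fraction of the ROI (Otsu by
default, fixed threshold switchable); normalisation is to ROI area, with
the heart-area alternative left to the caller via polygon measurements.

**Shape descriptors** come from the moments-fitted ellipse (axes with the
mask's second central moments — the standard "fit ellipse"), with
`roundness = 4·area / (π·major²)`, the inverse aspect ratio.

**Statistics.** Student's *t* is the pooled-variance test (Welch behind a
flag); Mann-Whitney is exact by enumeration for n₁+n₂ ≤ 16 without ties,
otherwise normal approximation with tie and continuity corrections.
Zero-variance and all-tied degenerate inputs return explicit p = 1 / 0
with a flag rather than NaN. No multiple-testing correction is applied —
contrasts are reported raw, per the assay family's convention — so
families of comparisons must be interpreted accordingly. Test choice per
contrast is a configuration decision, never inferred from the data.

## Problem sizes used in the recovery runs

`scripts/acceptance.py` and the recovery tests use the study conditions
(100 fps / 30 s angiography recordings, 200 fps valve and particle
recordings, 2 beats/s, noise σ 5) with these sizes, chosen as the
package's validation defaults:

- velocity: 6 s scenes at 2, 5 and 8 mm/s on a 48×512 px tube,
  1 beat/s (the transit between ROIs must fit within one beat period);
- beats/arrests: 10 seeds × 30 s with one 3 s injected arrest;
- accumulation: opening fractions 1.0 / 0.6 / 0.2 × 5 seeds × 30 s;
- continuity and tracking: 2 s particle scenes (10 and 20 particles) on a
  160×256 px field at 2.5 µm/px;
- kinematics: 5 s valve-label scenes at 200 fps;
- directionality: 256 px textures at coherence 0.8;
- statistics: all group sizes with n₁+n₂ ≤ 12 against full enumeration.

## Known limitations

- The two-ROI velocimeter cannot disambiguate transit times longer than
  one beat period (aliasing inherent to periodic packet trains).
- Gap measurement assumes the valve-label channel thresholds into exactly
  the two cell bodies; heavy labelling artefacts need pre-cleaning.
- Greedy linking is not globally optimal under dense crossings; the
  generator's scenes stay below the collision limit by design.
- The tube axis is a configuration input; no automatic axis estimation.
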