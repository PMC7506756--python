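# Methods

## Measurement model

The pipeline treats a pupillometry recording as an ordered sequence of
grayscale infrared eye frames at a fixed frame rate (default 30 fps;
frame `i` occurs at `i / fps` seconds, 0-based). Dark-pupil imaging is
assumed: the IR source sits off the camera axis, so the pupil is the
darkest region of the frame, darker than iris, sclera and skin. The
per-frame quantity of interest is the pupil's apparent area in pixels;
a frame in which no pupil is detectable (blink, segmentation failure) is
assigned area 0, and zeros are treated as "eye closed" throughout.

### Segmentation

The mask source is pluggable because the features downstream only need a
binary pupil-candidate map per frame. The shipped `threshold` backend
marks pixels strictly darker than `intensity_thr` (default 80 of 255),
then applies morphological opening followed by closing with a disk of
radius `morph_radius` (default 2 px). Opening removes sub-pupil speckle;
closing fills corneal-glint holes inside the pupil. The order is fixed
(opening first) so speckle cannot be inflated into blobs before removal.
The `external_masks` backend reads 0/255 PNG masks named by frame number,
for users with their own (e.g. CNN-based) segmenter.

Mask quality is scored by pixel IoU, with mIoU the unweighted mean over
frames. Two empty masks score IoU 1: on a closed-eye frame, predicting
"no pupil" is exactly right, and any other convention would penalize
recordings with many blinks.

### Pupil detection

Per frame: connected components (8-connectivity) of the mask become
candidates; each carries its outer contour, the hole-filled pixel count
CA (for raster regions the filled outer-contour polygon area and the
pixel count coincide), and its axis-aligned bounding box W×H. Filters,
both strict inequalities:

- area: keep iff CA > `CA_THR` (default 300 px);
- aspect: keep iff min(W,H)/max(W,H) > `AS_THR` (default 0.4).

The aspect ratio is symmetrized by min/max so tall and wide elongations
are treated alike; a near-circular pupil has ratio ≈ 1 and comfortably
survives, while eyelash shadows and lid edges (elongated) are removed.
The direction of this test deserves a flag: the keep-if-greater reading
is adopted because only under it does a circular pupil survive a 0.4
threshold; the removal of *elongated* candidates is the stated purpose
of the filter. An optional upper area bound `CA_MAX` is available but
disabled by default. Among survivors the largest CA is the pupil, ties
going to the first in row-major scan order.

The reported pupil size is the area π·a·b of a direct least-squares
ellipse fit to the outer contour (subpixel boundary at the 0.5 level),
not CA itself; the fit is robust to small boundary noise and gives the
physiologically meaningful elliptical model of an off-axis pupil.
Contours with fewer than 5 points cannot constrain a conic and the frame
is treated as no-pupil with a logged warning.

### Inflection points and accommodation speed

Pupil accommodation proceeds over seconds, so frame-to-frame differences
(33 ms apart) mostly measure noise. Instead the signal is reduced to its
turning points. Candidates are all sample-level extrema of the signal,
computed within each maximal non-zero segment independently — zero runs
are excised first because a 0 is sensor dropout/closure, not a pupil
size, and no swing may span a blink. Segment endpoints are included as
candidates (a truncated swing is still a swing; the alternative loses
the first and last accommodation event of every segment).

Selection is a greedy left-to-right scan: the first candidate anchors;
a candidate is accepted when its size difference from the previously
accepted point (1) alternates in sign against the previously accepted
difference and (2) exceeds the threshold δ in magnitude. A candidate
continuing in the same direction *replaces* the previous acceptance, so
each accepted point is the most extreme of its run — without this
refinement a noisy shoulder halfway up a rise would be frozen in as the
"peak". The output provably alternates with every |ΔS| > δ.

δ defaults to `auto` = max(5% of the interquartile range of the non-zero
sizes, 5·σ̂), where σ̂ = 1.4826·median|ΔS|/√2 over successive in-segment
differences — a robust noise-scale estimate. The IQR term adapts the
gate to the signal's scale (pixel counts vs normalized traces); the
noise floor is needed because with realistic frame noise the IQR term
alone sits below typical adjacent noise swings and promotes hundreds of
jitter extrema to inflections, inflating the speed estimate several-fold.
Five noise sigmas put the gate far into the tail of jitter-induced
differences while remaining an order of magnitude below genuine
accommodation swings.

Accommodation speed is then

    P = (1/N) Σₙ₌₁..N |S₍ₙ₊₁₎ − Sₙ| / (F₍ₙ₊₁₎ − Fₙ),  N = #points − 1,

in pixels/frame (a pixels/second convenience P·fps is also reported;
sizes are pixel areas and the denominator is frames, so "pixels/frame"
is the dimensionally honest unit). Fewer than two accepted points give
P = 0 by convention. Duplicate frame numbers are an error.

An optional moving-median pre-smoothing (`smoothing_window`, odd, default
1 = off at the function level) runs per segment before candidate
detection. The pipeline and demo use a documented analysis configuration
with window 5: the median kills single-frame segmentation glitches
without displacing extrema, and measured on synthetic noisy signals it
removes the upward bias that noise at the extremum values otherwise
contributes to P (noise adds ~2σ at each accepted peak value). Tiny
didactic examples keep smoothing off so raw extrema are inspectable.

### Blink frequency and eye-closed duration

Blink frequency = number of maximal zero runs / duration in seconds;
eye-closed duration = total zero frames, convertible to seconds and to
average closed time per second. Leading/trailing zero runs count as
blinks — a blink truncated by the recording boundary cannot be
distinguished from a complete one. An all-zero recording is one blink
spanning it. Canonical check: a 10-s, 30-fps series with zero runs of
6, 1, 5, 8 and 6 frames has 5 blinks → 0.5 blinks/s, 26 closed frames →
0.87 s (0.86 when truncated to the printed precision), 0.086 s closed
per second.

### Statistical comparison

Feature values from independent viewing sessions are compared per
feature between the reference condition and each modified condition.
Default: Welch's two-sample t-test, two-sided — sessions are independent
and variances need not match; Student's t, Mann-Whitney U, paired t and
Wilcoxon are selectable (paired designs per subject across conditions
are plausible, so the paired tests are exposed rather than assumed).
Identical samples yield p = 1 by convention (several tests return NaN
there). Stars: *** p<0.01, ** p<0.05, * p<0.1. No multiple-testing
correction by default (per-comparison reporting); `holm_adjust` is
available and opt-in. The condition summary table prints group means to
4 decimals.

## Synthetic data

`generate_signal` emulates the statistical structure the pipeline
assumes, not pupil physiology: area(t) = base + A·sin(2πt/T) + ε,
ε ~ N(0, σ²), clipped at 0, with blink onsets from a Poisson process,
each zeroing a uniform-length run of frames. Defaults — 30 fps, base
1200 px² (radius ≈ 20 px at 640×480), A = 300 px², T = 8 s (accommodation
evolves over several seconds), blink rate 0.3/s (a typical relaxed
viewing rate), blink length 5–10 frames (≈170–330 ms), σ = 15 px² (5% of
A) — give signals of the shape real traces show. Blinks are refractory:
an onset landing inside the previous blink is deferred one open frame
rather than merged, so the zero-run count stays Poisson(rate·duration)
and rate-recovery checks are unbiased. Transitions are instantaneous
(no partial-occlusion ramp), matching the zero-size treatment of
closures.

`render_frames` rasterizes each non-zero frame as a filled pupil ellipse
of exactly the requested area (axis ratio configurable, circular by
default, rotation fixed at 0 — the pipeline measures area, not
orientation) at a jittered center on an iris disk over skin background,
plus small saturated glint disks inside the pupil; blink frames are
featureless skin. Ground truth (true areas, rasterized masks, blink
flags, noise-free extrema and their mean inter-extremum slope) rides
along for every stage's oracle.

What the generator does **not** model — pupillary light reflex latency,
hippus, gaze-dependent pupil foreshortening, eyelid ramps, specular
structure, camera vignetting, head-slip — bounds what passing tests
show: the pipeline recovers what this model generates; performance on
real recordings depends on segmentation quality there.

## Numerical choices and degenerate inputs

- Strict `>` at both detector thresholds, by definition of the filters.
- Empty∧empty IoU = 1 (see above); IoU shape mismatch is an error.
- Ellipse fit failure or <5 contour points → area 0 with a warning,
  never NaN; areas are always finite and ≥ 0.
- `P` with <2 inflection points → 0; all-zero series → one blink run.
- Trace CSVs must be gap-free and sorted; gaps are an error, never
  silently filled. Floats round-trip bit-exactly (repr on write,
  round-trip parsing on read).
- RGB fixture inputs are converted with BT.601 luma weights
  (0.299, 0.587, 0.114); masks on disk are 0/255, in memory {0,1}.
- All generators use one `numpy` Generator per seed with a documented
  draw order; pipeline outputs are byte-identical per (config, seed).

## Problem sizes used in the shipped checks

End-to-end recovery runs 600 rendered frames at 320×240; noisy-signal
feature recovery uses 60-s signals (1800 frames); the null-calibration
of the statistical stage uses 1000 replicates of n = 15 per group; the
demo uses 8 recordings of 60 s per condition. These sizes give stable
estimates (Monte-Carlo error well inside the asserted tolerances) while
keeping a full run interactive.

## Known limitations

- The classical threshold backend assumes the pupil is the darkest
  object; heavy mascara, shadows, or off-axis IR can violate this — use
  the external-mask backend with a trained segmenter in that case.
- Aspect/area thresholds (300 px, 0.4) are resolution-dependent: they
  suit ~640×480 eye crops with a 15–25 px pupil radius and should be
  rescaled for other optics.
- Accommodation speed is reported in pixel units; calibration to
  millimeters (and hence across subjects/rigs) is out of scope.
- Segments shorter than 3 frames cannot be analyzed for inflections.
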