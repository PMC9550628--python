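# Methods

This note documents the models, algorithms, parameter choices and
limitations of eventscope: what is simulated, how events are detected
and localised, how the coordinate calibration works, and what the
synthetic benchmarks do and do not demonstrate about real recordings.

## The acquisition model

The package models a two-modality instrument: a camera-based widefield
surveillance channel (default 100 nm pixels, 50 ms frame period) and a
point-scanning high-resolution channel that can image a small region of
interest (ROI, default 3 × 3 µm² at 25 nm pixels) anywhere in the field.
The controller runs one detection pipeline on every widefield frame; on
a detection it maps the widefield coordinate into scan space, requests a
scan stack centred there through a callback (so a hardware backend could
replace the simulator unchanged), stores the evidence bundle — the
widefield frames leading up to the event, the scan stack, and a log
entry — and resumes surveillance. Pipeline state is rebuilt from scratch
after every trigger because the widefield stream is conceptually
interrupted by the scan: a frame-difference map across that gap would
compare non-adjacent frames.

Run modes: `endless` (trigger and continue), `single_trigger` (stop
after the first scan), `validation` (detect, never scan) and
`visualization` (validation plus retention of each frame's preprocessed
map). Validation performs the same post-trigger state reset as the
triggering modes so that all modes observe the identical event stream on
the same deterministic source — this equivalence is itself a test.

Per-event analysis and transform durations are measured wall-clock and
recorded as metadata. They characterise the host they ran on, not the
method, so no timing is ever asserted, and the CLI writes logs with the
timing values nulled (fields present) to keep reruns byte-identical.

## Detection pipelines

All three pipelines share primitives: Gaussian smoothing (reflective
boundaries, so edges do not darken and fake ratiometric peaks),
background reduction by subtracting a wide Gaussian blur (clipped at
zero), maximum-filter peak finding (a pixel is a peak when it equals its
own windowed maximum; connected plateaus collapse deterministically to
the lexicographically smallest pixel), salience thresholding, and greedy
nearest-neighbour track linking (candidate pairs sorted by distance,
matched one-to-one, links beyond `max_link_distance` rejected, gaps up
to `memory` frames bridged). Greedy linking rather than global optimal
assignment is deliberate: at the emitter densities involved the two
agree, and greedy is simple, fast and deterministic.

**rapid_signal_spikes.** The comparison map is the per-pixel ratio of
the smoothed current to the smoothed previous frame with a floor ε on
the denominator; a ratio makes the trigger threshold a unitless number
(> 1) independent of local brightness, which is what makes one
threshold usable across a heterogeneously labeled cell. A normalised
difference map is available as a config alternative. Two gates suppress
division noise where the denominator is small: the binary sample mask
(mean of ten frames, globally thresholded) and a minimum raw-intensity
gate. Peaks within the border-exclusion zone (half the scan ROI
footprint) are discarded so a triggered scan always fits inside the
field. Events are returned salience-descending and the controller
consumes the first, matching single-scanner semantics.

**dynamin_rise.** Peaks of the smoothed, background-reduced frame are
gated between a low threshold (noise) and a high threshold (large
bright clusters), then linked into tracks. For each track, the mean
intensity in a (2a+1)² box around the peak is stored per frame. When a
track reaches exactly N detections, it fires if and only if
`I_last / I_first ≥ ρ`; it is then retired either way. The ratio uses
first-vs-last rather than requiring monotonicity, which tolerates
frame-level noise in the rise. The box statistic is the mean (not max):
it is less noisy and scale-cancelling in the ratio.

**vesicle_proximity.** Detection and linking as above; the event logic
runs on track pairs. "Disappeared" means closed under the memory rule,
with the disappearance dated to the last detection; recency requires
`frame − last_detection ≤ k`. "Consistently present" requires
detections in at least `q·L` of the last `L` frames for both tracks.
The movement condition takes "accumulated vectorial distance" as the
magnitude of the summed step vectors (net displacement) and "absolute
distance" as the sum of step magnitudes (path length); requiring both
≥ a threshold distinguishes genuine travel from jitter in place. Each
(disappeared, survivor) pair fires at most once. The event is placed at
the disappeared track's last position — the physically best estimate of
where the pair became unresolvable.

## Coordinate calibration

The widefield→scan map is a general third-order 2-D polynomial (ten
coefficients per axis), enough to absorb the smooth distortions optical
relays introduce while remaining cheap to evaluate (well under a
millisecond per point). Control points are matched bead detections in
the two modalities. Inputs are normalised to [−1, 1] before building
the monomial design; without this, cubic monomials on raw
several-hundred-pixel coordinates make the normal equations numerically
useless. The fit is damped iterative least squares seeded by the linear
solution; because the model is linear in its coefficients, the two must
agree to ~1e−8 relative, and that agreement is a test, not an
assumption. Transforms serialise to JSON losslessly (coefficients plus
normalisation) and report their training residual.

At the benchmark conditions — 100 beads across an 800 px field,
isotropic 0.5 px detection noise at 100 nm pixels — the mean per-bead
registration error measures ≈ 55–65 nm, consistent with a
1,000-replicate Monte-Carlo ensemble at the same design, and of the
same order as what a real bead calibration at this pixel size achieves.

## The scene simulator

The simulator is the package's stand-in for the microscope and
defines the benchmark study conditions.

* **Camera model**: expected counts → Poisson draw → additive Gaussian
  read noise (σ = 2 counts) → clamp at zero and round to integers
  (sCMOS-like).
* **Spikes** multiply the local baseline by
  `1 + A·exp(−(t−t_on)/τ)` over a Gaussian footprint, so the scheduled
  amplitude *is* the peak dF/F₀ irrespective of local brightness.
  Benchmark kinetics: A = 1.0, τ = 400 ms at a 50 ms frame period.
* **Rising spots** ramp linearly (or sigmoidally) from I₀ to r·I₀ over
  M frames and hold.
* **Vesicles** take 2-D Brownian steps with per-axis std `sqrt(2 D Δt)`
  (Einstein relation; ensemble MSD 4DΔt). A merge script overrides one
  vesicle's path with a straight approach onto its target; from the
  merge frame on, only the target is rendered (the pair is
  unresolvable) and the mover's truth trajectory becomes NaN.
* **Bead fields** scatter sources uniformly and apply the ground-truth
  transform plus isotropic detection noise.
* **Scan rendering** resamples the same truth emitters at scan
  resolution with a narrow Gaussian PSF (default FWHM 40 nm). Scan
  coordinates share the widefield pixel frame, so an identity transform
  means identical coordinates; positions are frozen at the trigger
  frame across the stack's frames.

All generators are pure functions of (spec, seed): same inputs, bit-
identical stacks.

**Benchmark conditions.** The spike benchmark uses ten 200 × 200 px,
100-frame movies with ten spikes each on a flat baseline chosen so that
the spike's peak amplitude equals five per-pixel noise standard
deviations (SNR 5): B with B² = 25·(B + σ_read²) ≈ 28.5 counts. The
vesicle benchmark scripts an 18 px approach over 16 frames; because the
proximity event is localised at the disappeared track's last detected
position, and two Gaussian emitters cease to be separate local maxima
at roughly twice their effective width, the benchmark renders vesicles
with a 0.7 px footprint and detects with 0.4 px smoothing (window 3) so
that tracks stay resolvable to ≈ 2.5 px — inside the scenario's 3 px
localisation tolerance. These are well-sampled point emitters at the
high SNR of the rendered labeling, not a tuned detector.

**What the simulator does not emulate.** Real neurite morphology and
heterogeneous labeling; moving filopodia-like structures (the dominant
false-positive source in live neurons); photobleaching during
surveillance; depth-dependent background; camera fixed-pattern noise;
scan-channel photophysics beyond a Gaussian PSF. Passing benchmarks
therefore demonstrate the correctness and calibration of the
algorithms under controlled conditions — not field performance on live
cells, where detection ratios are known to be materially lower.

## Post-acquisition analysis

* **dF/F₀**: disc-mean intensity per frame; F₀ is the mean of the
  first k frames (k = 1 reproduces the F(t₀) convention). Invariant
  under global gain by construction.
* **Detection quality**: greedy one-to-one matching of detections to
  annotations, closest in time then space within (r, t) tolerances;
  reports matched/detections (true-positive ratio; undefined with no
  detections) and matched/annotations (detected fraction).
* **Bleach correction**: each frame's empirical intensity distribution
  is monotonically remapped onto a reference frame's (histogram
  matching). No kinetic model is assumed; intensity ordering within a
  frame is preserved.
* **Cluster segmentation**: 1 px Gaussian smoothing, timelapse-constant
  global threshold, one binary erosion with a 3 × 3 square element,
  8-connected components, area filter > 0.015 µm². Aspect ratio is the
  major/minor axis ratio of the second-moment equivalent ellipse
  (floored at 1; ∞ for degenerate 1-px-wide regions); centroid is the
  unweighted binary centroid, reported in µm. Note the erosion shaves
  ≈ 1 px per side, which biases the aspect ratio of small elongated
  regions upward — the test fixtures use regions large enough that the
  bias is below the tolerance.
* **Trace linking**: frame-to-frame minimum-distance matching with a
  hard 0.3 µm/frame limit and no gap memory; unmatched regions end or
  begin traces. The trace seeded by the largest first-frame cluster is
  flagged for MSD analysis.
* **MSD**: default is the mean *squared* displacement in µm², the
  convention consistent with reporting MSD in area units; a
  `literal_distance` mode returns the mean un-squared distance in µm
  for comparison with descriptions phrased that way. The mode is
  recorded in every output row.

## Numerical and degenerate-input choices

Convolutions use scipy's reflective boundary mode throughout. Peak
plateaus collapse to the lexicographically smallest pixel (row, then
column); peak lists sort salience-descending with (row, column)
tie-breaks — all ties deterministic. The ratio map's division floor ε
defaults to 1 count. Ten control points is the hard minimum for the
20-coefficient transform fit; rank-deficient designs (collinear or
clustered points) are rejected with advice rather than silently
producing a wild extrapolation. An event whose scan ROI would leave the
field is skipped with a logged warning (border exclusion should make
this unreachable). Mask recording insists on exactly ten frames, the
instrument's fixed procedure; overrides must be explicit.

## Problem sizes

The benchmark sizes used by the test suite and the reproduction script
— 200 × 200 px spike movies, 150 × 150 px vesicle scenes, 800 px
calibration fields with 50–100 beads, 1,000 Monte-Carlo replicates,
50 × 100-step Brownian ensembles — were chosen as the smallest scales
at which the statistical assertions (precision/recall, envelopes, MSD
ratios) are stable across seeds. Real instruments survey larger fields
(e.g. 800 × 800 px); all algorithms are resolution-independent and take
their geometry from the scene spec.

## Known limitations

* Track linking is greedy, not globally optimal; at high emitter
  density identity swaps become possible. The benchmarks stay in the
  regime where this does not occur.
* No sub-pixel peak localisation: event coordinates are pixel-centre
  positions, adequate for centring a micrometre-scale scan ROI.
* The vesicle-merge event location is limited by two-point
  resolvability of the widefield channel (~2σ of the effective PSF),
  not by the linking logic.
* The scan renderer is a toy: no depletion photophysics, no
  photobleaching, 2-D only.
* `validation`/`visualization` modes are the only ones available for
  archived TIFF input, since stored data cannot be scanned.
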