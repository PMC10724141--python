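# Methods

`celledge` quantifies subcellular morphodynamics from multi-channel
fluorescence time-lapse movies: where and when a cell's edge protrudes or
retracts, how a membrane-proximal fluorescent signal organizes around that
motion, and how whole cells migrate.  This note records the models,
conventions, parameter choices and numerical decisions behind each stage,
and what the synthetic-data tests do and do not demonstrate.

## Edge mapping

**Segmentation.** The cell is identified per frame from a cytosolic
volume-marker channel by Otsu (or fixed) thresholding, hole filling, and
keeping the largest connected component; components below `min_area`
(default 100 px) raise an error naming the frame.  Masks touching the image
border are rejected rather than cropped — edge velocity at a clipped
boundary is undefined.

**Boundary parameterization.** The 0.5 iso-contour of the binary mask
(sub-pixel, via marching squares) is smoothed with a circular Gaussian along
the contour (`smooth_sigma = 2` vertices by default) to suppress the pixel
staircase, oriented counter-clockwise, and resampled to `n_positions`
(default 100) equal-arc-length points.  Position indices must mean the same
piece of edge in every frame: frame 0 starts at the boundary point of
maximal x on the horizontal through the contour centroid, and each later
frame starts at the contour point nearest the previous frame's start.  This
local rule needs no global registration and is exact for stationary shapes.

**Edge velocity.** With `D_t(x)` the distance from `x` to frame `t`'s
boundary polyline, signed positive inside the cell, the velocity sample
between frames `t` and `t+1` at position `p` is

    v(p, t) = 1/2 [ D_{t+1}(x_{p,t}) − D_t(x_{p,t+1}) ] · pixel_size · 60 / Δt

in μm/min, positive outward.  The symmetrized two-point form was chosen over
sampling only the next frame's distance field because it is exactly
antisymmetric under time reversal (playing a movie backwards negates its
velocity map entry-wise) and halves single-frame digitization error.
Distances are measured to the full-resolution smoothed polyline, not the
resampled polygon, to avoid chord-shortening bias.  The sample is attributed
to the midpoint time `(t + 1/2) Δt`.

*Accuracy.* On a disk grown 1 px/frame the map mean is within ~1% of the
analytic 0.39 μm/min, but individual entries deviate by up to ~20–25%: the
1-px ring between two digitized circles genuinely varies between 0 and 2 px
in local width, so per-entry accuracy is digitization-limited for any
estimator that sees only binary masks.  On synthetic star-shaped cells
(amplitude ≈ 8 px) the measured map correlates with the analytic ground
truth at Pearson r ≈ 0.97–0.99.

**Inward signal band.** Fluorescence is averaged over mask pixels whose
distance-map value is at most `round(band_depth / pixel_size)` pixels
(default 3 μm → 12 px at 0.26 μm/px), i.e. a band extending from the edge
*inwards only*, so membrane-recruited signal is not diluted with
extracellular background.  Each band pixel is assigned to the nearest
resampled boundary point (a discrete Voronoi partition along the contour);
positions left empty are imputed by circular interpolation and flagged.  The
enrichment denominator, `whole_cell_mean`, averages *all* mask pixels over
all frames.  The central/peripheral split uses the same distance map with a
pixel count (default 5 px = 1.3 μm at 0.26 μm/px).

## Signal–motion coupling

**Labelling.** Map entries with velocity strictly above +0.075 μm/min are
protrusion, strictly below −0.075 μm/min retraction, otherwise neither.  A
value exactly at a threshold is "neither".  No temporal smoothing is applied
before labelling by default (a moving-average window is available).

**Cross-correlation.** Pearson r between `signal(p, t+ℓ)` and
`velocity(p, t)` pooled over all valid (position, time) pairs, for lags
`ℓ ∈ [−max_lag, +max_lag]`.  Positive lag means the signal follows the edge
motion.  Lags with zero variance in the overlap are reported as missing
(NaN), never as 0.  The `extremum_lag` is the lag of the correlation
*maximum* — appropriate for signals recruited during protrusion; a
retraction-recruited signal anticorrelates and `trough_lag` is the extremum
to read.  The full pipeline averages adjacent signal-map frames before
correlating so that both maps sample midpoint times and the extremum falls
on an integer lag.

**Enrichment functions.** Enrichment at shift `s` is the mean of
`signal(p, t+s)` over protrusion-labelled (retraction-labelled) entries,
divided by the whole-cell mean, minus 1, in percent.  Sliding `s` over a
symmetric range gives the time-shifted enrichment function; the shift of the
protrusion peak estimates the recruitment delay.  Sensor enrichment can be
normalized to a control construct multiplicatively,
`e' = ((1+e_s/100)/(1+e_c/100) − 1)·100`; the ratio form cancels
band-geometry biases common to both channels (an additive form was the
alternative; the multiplicative one was chosen because the underlying
quantity is itself a ratio of means).

**Cycle durations.** The velocity map is rescaled (circular linear
interpolation) to 100 circumference positions.  Per position, a protrusion
onset is a protrusion-labelled frame whose predecessor is not (the first
frame qualifies); the cycle closes at the first subsequent
retraction-labelled frame, tolerating intervening "neither" frames.  A new
protrusion onset before any retraction restarts the open cycle, and cycles
still open at the end of the recording are discarded.  For a sinusoidal
velocity with amplitude well above threshold the mean duration equals half
the oscillation period (the first crossing below −θ follows the first
crossing above +θ by exactly T/2), which the tests use as the analytic
oracle.

## Biosensor kinetics

Raw membrane-proximal sensor intensity confounds GTPase activity with cell
volume and illumination artifacts.  Two normalizations are provided:

* simple: `A(t) = (I(t) − I_BG(t)) / (Ī₀ − Ī₀,BG)`, baseline mean 1;
* control-corrected: the simple form minus the identically normalized trace
  of a co-expressed freely diffusing control fluorophore, baseline mean 0.

`Ī₀` denotes the mean over the pre-perturbation baseline frames (default:
all frames before onset).  Backgrounds are per-frame means outside the mask
dilated by 10 px (per-frame estimation is strictly more general than a
single constant and reduces to it).  Both forms are invariant to channel
gain; the corrected form also cancels any artifact shared by sensor and
control — the bleaching demo in `analysis/05_sensor_kinetics.py` shows the
simple trace drifting to ~0.74 under exponential bleaching while the
corrected trace stays within ~3·10⁻⁴ of zero.  Windowed responses are
mean(post) − mean(pre) over `n_post`/`n_pre` frames around an onset.

## Migration

Nuclei detections (labelled regions per frame) are linked by greedy
nearest-neighbour assignment in ascending distance order with a gate
(`max_link_distance`, default 20 μm), no gap closing and no split/merge
handling — adequate for sparse seeding, and a documented limitation for
dense or dividing populations.  Tracks whose centroid approaches within one
object radius of the field border are flagged incomplete and excluded from
cohort summaries by default (such cells may leave the field).  Per track:
distance (path length), displacement (start→end), directionality
(displacement/distance ∈ [0,1]), and mean speed.  The default cohort window
is 240 frames at 1 frame/min (4 h).

## Synthetic data generator

The generator emulates the statistical structure of a TIRF recording of an
adherent epithelial cell, with every downstream estimate checkable against
closed-form truth:

* **Shape.** Star-convex outline `R(θ,t) = R₀ + A·sin(2π(t − φ(θ))/T)` with
  per-lobe phase offsets φ, piecewise constant over `n_lobes` angular
  sectors with smoothstep blends over 30% of a sector — spatially local
  protrusion/retraction patches with an analytic radial velocity
  `∂R/∂t = A·(2π/T)·cos(·)`.
* **Channels.** Volume marker: uniform intensity inside the mask over
  background, plus i.i.d. Gaussian noise.  Sensor: the volume channel
  multiplied, within a 3 μm inward band, by
  `1 + gain · v̂(θ, t − lag)` with `v̂` the velocity normalized to its
  maximum — membrane recruitment proportional to (delayed) edge motion.
  An optional exponential bleach factor applies equally to both channels.
* **Defaults.** 0.26 μm/px, 40 s frame interval, R₀ = 13 μm, A = 2 μm,
  T = 600 s, 6 lobes, intensities 100/10 AU, noise 2 AU (2%): a cell of
  realistic size whose edge patches cycle on the minutes scale, resolved at
  15 frames per period.
* **Ground truth.** The analytic velocity map is sampled on the *measured*
  map's grid: the extractor's parameterization rules (equal arc length,
  centroid-row start, nearest-point continuity) replayed on the analytic
  outline, at frame-midpoint times.
* **Toy maps** bypass imaging: sinusoidal per-position velocity with random
  phases and a signal equal to `1 + gain·velocity` evaluated `lag` frames
  earlier, both on the same integer frame grid so constructed lags are
  recovered exactly.
* **Migration walks.** Headings evolve by uniform turns scaled by
  `1 − persistence`; step lengths are Rayleigh, so zero persistence gives
  isotropic Gaussian steps and persistence 1 gives straight lines.

What passing these tests shows — and does not.  The generator reproduces the
geometry and timing structure the pipeline measures (oscillating local
edges, delayed band-limited recruitment, volume artifacts, migration
persistence) and therefore validates the measurement chain end to end:
known lags of 0–160 s are recovered within one 40 s frame by both the
enrichment peak and the correlation extremum, and uncoupled sensors show
<0.5% enrichment at every shift.  It does not emulate textured cytoplasm,
uneven illumination, focal drift, segmentation ambiguity at filopodia, or
non-stationary oscillation periods; performance on real recordings depends
on those factors and on segmentation quality in particular.

## Problem sizes and numerics

Test and analysis runs use 96–160 px frames, 8–100 frames per movie, 100
boundary positions, and 10⁴ random tracks for the metric-bound checks —
sizes chosen so the full suite and the analysis scripts re-run in seconds
while leaving the estimators in the same regime as real data (cell diameter
~100 px, ~15 frames per oscillation period).  Degenerate inputs are errors,
not silent results: constant frames under Otsu, masks on the image border,
zero baseline denominators, empty enrichment overlaps (missing value plus
warning, never 0), and misordered thresholds all raise with the offending
field or frame named.  All randomness flows through a single integer seed
per generator call; identical seeds give bit-identical movies, and the
pipeline writes numerically stable CSV (%.12g) so identical configurations
reproduce identical files.
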