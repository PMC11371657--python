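# Methods

This note documents the models, rules and numerical choices behind the
`twitchtaxis` pipeline, and what its synthetic validation does and does
not demonstrate about real data.

## Coordinate and unit conventions

Lengths in µm, time in minutes, concentration in mM.  Image x runs
rightward (columns), y downward (rows), origin at the top-left pixel
corner; a pixel's centre sits at `(index + 0.5) × pixel_size`.  Pixel
size defaults to 0.1 µm/px (no camera calibration is published for this
kind of set-up; the value is configurable).  Orientations are axial
angles from +x in [0, π); **pole 1** of a cell is the body-axis endpoint
at `centroid + (length/2)·(cos θ, sin θ)`, pole 2 the opposite end.  The
gradient axis is a configurable unit vector (default +y); "toward higher
concentration" means a positive projection on that axis times the
current gradient sign, which flips at each swap (epochs are half-open
frame intervals).

## Gradient models

* **Dispersion front.**  `C(x,t) = C_MIN + ΔC·S((x − Ut)/L)` with
  `S(z) = (1 + erf(√π z))/2`.  The erf is the long-time solution of 1-D
  advection–dispersion; the √π argument scaling makes `S′(0) = 1`, so the
  mid-front spatial gradient is exactly ΔC/L and the nominal length
  scale L = Uτ, the characteristic gradient ΔC/L and the mean temporal
  gradient ΔC/τ are mutually consistent.  Only the endpoint
  concentrations and the length scale are treated as ground truth; no
  molecular diffusivity enters any reported number.
* **Dual-flow cross-channel gradient.**
  `C(y) = (C_source/2)(1 + erf(√π s y/w))` with width scale
  w = 100 µm and epoch sign s = ±1: centreline value C_source/2,
  mid-channel slope C_source/w (0.02 mM µm⁻¹ at 2 mM).
* **Concentration switch.**  The same ramp in time with timescale
  τ = 1.5 min between 0.84 and 1.16 mM.
* "Mean dC/dt over the passage/ramp" is defined as the total
  concentration change divided by the nominal timescale τ — the same
  convention behind the printed design numbers.
* Dye intensity is an affine map of concentration; the inverse map clips
  to [0, C_MAX] with a logged warning.

## Synthetic microscopy generator

The generator emulates the study conditions: cell channel at 7.5
frames min⁻¹, fluorescence and dye at 0.5 frames min⁻¹ (an integer
1:15 subsampling on a shared clock; the alternating-gradient experiments
used 0.4 frames min⁻¹, but a non-integer frame ratio would break the
shared-clock assumption), 0.9 µm wide cells of length 2–3.5 µm, creep
speed 0.2 µm min⁻¹ along the fixed body axis, single-frame jumps 20×
faster with probability 2×10⁻³ per frame, Poisson reversals at
5×10⁻³ min⁻¹ (of order one reversal per several hours), stationary
fraction 7.5 % with 0.02 µm/frame Gaussian jitter, gradient direction
swaps every ~45–60 min (default 44 min, aligned to a fluorescence
frame).

Cells are blurred (σ = 0.1 µm) constant-intensity spherocylinders;
foci are 2-D Gaussians (σ = 0.15 µm) anchored width/4 inside the pole
tip, laterally offset up to ±0.3 µm to exercise the multi-line profiler;
focus amplitude is 4× the cytoplasmic level with ±20 % per-cell
variation.  Noise defaults to Gaussian with σ = 2 % of the focus
amplitude; validation runs are noise-free.  The cell channel is
quantized to 8 bit to keep stacks small — segmentation accuracy is
blur-limited, not quantization-limited.

Design choices that matter for interpretation:

* **Polarity timelines are static except for scripted events.**  Real
  cells show spontaneous localization dynamics; the generator produces
  polarity changes only through explicit event scripts so that an
  event-free run is a true negative control.  Consequently the closure
  tests demonstrate rule fidelity (every scripted event recovered, no
  false events from tracking or profiling artifacts), not robustness to
  spontaneous fluctuations — the pre-existing-localization veto is
  exercised by construction, not statistically.
* **Scripted-event cells** are placed outside the centreline dead zone,
  drawn with body axes ≥ ~37° from gradient-orthogonal (so the
  up-gradient pole is well defined), and motile neighbours are steered
  so their (straight, axis-bound) motion corridors avoid them — a merge
  with a passing neighbour would break the event cell's track, which is
  exactly what the paper-style manual annotation avoids by eye.
  Movement-trigger events step 1.1 cell widths per frame along the
  gradient for two frames, with the polarity change following two
  fluorescence frames later.
* Border contacts of motile cells reflect the travel direction; these
  reflections are recorded separately from stochastic reversals in the
  ground truth.
* Real-data features **not** emulated: photobleaching, uneven
  illumination, stage drift, cell growth and division, dense clusters,
  cell–cell mechanics.  Passing tests therefore say nothing about those
  regimes.

## Detection, tracking, kinematics

Segmentation is a global Otsu threshold plus connected components —
deliberately simple, standing in for the heavyweight trackers used on
real data and adequate for clean synthetic frames.  Pose: centroid and
principal axis from the pixel-coordinate covariance; length and width
are the component extents along/across the axis plus one pixel.
Linking is greedy nearest-neighbour (max step 2 µm/frame, zero gap
tolerance).  At the synthetic densities used, transiently touching cells
merge into one component; such frames are flagged as contacts (footprint
length or width > 1.45× the population median) and excluded from
polarity analysis, mirroring the cluster-exclusion filters used on real
data.  Per-frame evaluations against ground truth therefore use
per-frame position matching, so linking identity errors are measured
separately from classification errors.

Track filters: mean fluorescence under the footprint ≥ 3× the background
median (drops detritus) and aspect ratio ≥ 1.4 (boundary inclusive;
ensures both poles are surface-attached).  Motility classes: mean speed
< 0.038 µm min⁻¹ ⇒ stationary; NGDR < 0.04 ⇒ excluded jostling;
smoothed-orientation angular velocity > 0.073 rad min⁻¹ sustained
> 2 min ⇒ excluded rotating; else motile.  Axial angles are unwrapped
(mod π) before first-order Savitzky–Golay smoothing over a 20 min
window; angular velocity comes from central differences of the smoothed
series.  The reversal detector (a documented stand-in, since the
original detector lives in external tracking software) logs a reversal
where summed displacement directions over the two frames before and
after differ by > 150°, merging detections closer than the persistence
window.

## Polarity profiling and classification

Ten parallel lines at 0.09 µm spacing (spanning ~0.9 µm, one cell
width) sample the fluorescence image by bilinear interpolation at 0.1 µm
arclength steps; the profile is the per-arclength maximum.  Pole windows
cover the outer tenth of the length, the normalization window the
central quarter; I_k = pole max / central mean.  Rule order is fixed:
mid-cell (pre-division) exclusion, then the I_MIN thresholds (strict
inequalities), then the bipolar→unipolar ratio re-assignment.  The
mid-cell exclusion requires the central mean to exceed both raw pole
maxima by 10 %: division-site accumulations are several-fold brighter
than cytoplasm, whereas in signal-free cells the pole maxima sit
marginally below the central mean purely because intensity rolls off at
the rounded pole tips.

I_MIN and the ratio threshold are chosen per dataset (an automated
stand-in for choosing them by visual inspection): a Gaussian KDE of the
pooled log pole intensities and of the log pole ratios, density
zero-padded so boundary modes count, anti-mode between the two most
prominent modes; unimodal distributions fall back to the defaults
(I_MIN = 2, ratio 3) with a warning, and the histograms are returned for
operator review.  Pole windows always use the cell-channel pose length;
in the synthetic data the fluorescence footprint is identical by
construction.

## Repolarization events

All rules run per cell relative to the last gradient swap.  Stationarity
is monitored along the gradient axis from the first frame of the new
gradient to the event (and ≥ 3 frames before it): no two consecutive
same-sign steps each > 0.45 µm, no net excursion > 0.9 µm (the nominal
cell width, configurable).  Initial polarity is the majority class of
the 4 fluorescence frames preceding the swap, 2–2 ties broken by the
immediately preceding frame; mid-cell frames are never counted and, when
present, restrict counting to frames after the division.  Trigger A
(fluorescence clock) fires at the first frame whose unipolar class at a
new pole holds in ≥ 2 of 4 consecutive frames; trigger B (cell-channel
clock) at the first of ≥ 2 consecutive same-sign gradient-axis steps
each ≥ one cell width; the earlier trigger defines the event (polarity
wins ties), with the stationarity window ending just before the
movement for trigger B, since there the movement *is* the event.  Events
are vetoed if the new pole was already unipolar in ≥ 2 of the 4 pre-swap
frames or in the frame immediately preceding the swap.  Two
admissibility guards reject records an annotator could not verify: no
pre-swap fluorescence coverage (the veto cannot be assessed) and
unstable footprint length across the track (> 25 % from the median — the
signature of a transient merge).  Correctness compares the analytic
concentration at the two pole positions at the event time; the temporal
change compares the pre-swap concentration at the cell with C_MAX/2,
with a dead zone of 0.1× the gradient width scale (10 µm) around the
centreline where the sign is not assignable (no cutoff is published;
this is a package choice).  The scan horizon runs to the end of the
track.

## Count statistics

Reversals are Poisson per trajectory point: Garwood intervals
`[γ_{α/2}(n_r), γ_{1−α/2}(n_r+1)]/n_t` (exact coverage at λ = 50 is
95.3 %).  Two-sample comparisons use the conditional exact Poisson test;
the exact binomial test uses the minimum-likelihood two-sided
convention.  Proportion intervals are Wilson score (the published
method is unstated; exact coverage at p = 0.85, n = 171 is 94.7 %).
Trials are treated as independent across cells and time points, matching
the stated assumption of the original analyses; no repeated-measures
correction is applied.

## Validation problem sizes

The end-to-end closure scenario uses 200 cells on an 80×80 µm field for
90 min (675 cell-channel frames, 45 fluorescence frames) with 12
scripted events (9 correct / 3 incorrect, 3 movement-triggered) and one
gradient swap — large enough to exercise every rule and the calibration
(> 5,000 polarity records) while a full simulate-and-analyse cycle stays
around a minute.  Unit tests use smaller fields and durations chosen so
the specific property under test is not confounded (e.g. the
detection-recovery test runs at a spacing where cell crossings are rare,
the regime the greedy linker is designed for).  Exact-test checks
enumerate all instances up to n = 25; interval coverage uses 10⁴
Monte-Carlo replicates; the type-I-error check uses 10³ seeded
two-interval comparisons.

## Known limitations

* Greedy nearest-neighbour linking swaps identities when cells cross;
  rate denominators are unaffected but long-track statistics on crowded
  fields should use a stronger tracker.
* The per-interval reversal counts behind the published
  non-significance p-values are not public, so those exact values cannot
  be recomputed — only the type-I behaviour of the test is validated.
* Threshold calibration assumes a bimodal pole-intensity population;
  datasets dominated by one class fall back to defaults.
* The event rules are validated against scripted, noise-free dynamics;
  sensitivity to fluorescence noise and spontaneous polarity
  fluctuations is configurable but not part of the acceptance surface.
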