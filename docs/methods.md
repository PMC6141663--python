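# Methods

This note documents the models, conventions and numerical choices behind
`vesiquant`, and what the synthetic-scene tests do and do not establish
about real recordings.

## Conventions

All pixel coordinates are 0-based, pixel-centered, `(row, col)`.  Time is
expressed relative to stimulus onset (`t = movie_clock − stim_onset`), so
"before stimulation" means `t < 0`.  Intensities are arbitrary camera units
("AU") and are never rescaled implicitly; rules stated in AU (such as the
1,000-AU synapse-selection criterion) therefore apply to raw
background-subtracted values.

Background is modelled as a per-frame scalar: the mean of a user-supplied
background region, or the per-frame intensity mode (1-AU histogram bins
centred on integers) when none is given.  Negative values after subtraction
are clamped to zero.  This is the simplest model the scene generators can
invert exactly; it does not emulate rolling-ball or other spatially varying
corrections.

## LDCV fusion detection and classification

Vesicle puncta are detected on a robust time projection (temporal median of
the pre-stimulus frames) as local maxima of a difference-of-Gaussians
band-pass (`sigma` and `1.6 sigma`, default `sigma` 1.3 px), refined to
sub-pixel precision with per-axis parabolic interpolation, with a minimum
pairwise separation of `2 sigma` (brighter peak wins).  Footprint vesicles
in TIRF are docked, so spots are modelled as immobile and traces are read
at fixed positions.

Photometry uses a disk/annulus scheme around each spot: the trace is the
mean intensity in the central disk (radius `1.5 sigma`) minus the mean in
the surrounding annulus (`2–4 sigma`).  The annulus subtraction cancels any
offset shared by both regions — in particular the positive bias that
clamping noisy frames at zero leaves behind — so the trace of a vanished
punctum fluctuates around zero.  The apparent spot width is obtained by
inverting the annulus/disk intensity ratio through the rendered Gaussian
profile; because both quantities are region means, this estimate tolerates
far more pixel noise than a second-moment width.

Event classification operationalizes two qualitative signatures with
explicit thresholds, all exposed in `AnalysisConfig`:

* **full fusion** — the trace falls from ≥ 50% to ≤ 10% of its trailing
  running median (1-s window) within `full_fusion_max_duration`
  (default 0.2 s) and stays below 50% for ≥ 1 s;
* **kiss and run** — the trace rises to ≥ 1.5× the running median for at
  most 0.5 s, the apparent width concurrently grows ≥ 1.3× (the released
  cargo cloud), and the punctum is subsequently lost.

Durations are tested in seconds, not frames, so frame rates other than the
default 10 Hz work unchanged.  The scan is chronological and a
kiss-and-run onset takes precedence over the drop that follows it, which
prevents the post-transient loss from being double-counted as a full
fusion.  At most one event is reported per spot.  Events in the
pre-stimulus phase are counted in the cumulative curve, with the protocol
phase recorded per event.

Cumulative exocytosis is the event-count step function scaled by
`cohort_mean_area / footprint_area`: division by the cell's own footprint
removes cell-size dependence, multiplication by the cohort mean restores a
count-like scale comparable between groups (the curve is invariant under a
common rescaling of all areas).  Release probability is
`n_events / n_vesicles` at the footprint.

## SypHy trace analysis

Synapses are immobile puncta that respond to NH4Cl with a sharp rise:
candidates are detected on the mean image of the NH4 window and kept when
the NH4-window mean is ≥ 2× the pre-NH4 mean and the centroid drifts ≤ 1 px
across the movie.  Drift is measured on segment-averaged images (five
segments) rather than single frames, so frame noise does not masquerade as
motion while slow drift is still caught.

Each ROI trace (mean over ROI pixels, after background subtraction) is
normalized to its own maximum inside the NH4 window — the total vesicle
pool — which makes every downstream quantity invariant to expression
level.  The response time is the first crossing of
`baseline_mean + 2 × baseline_SD` sustained for ≥ 2 consecutive frames.
The baseline window defaults to [−10 s, −1 s]; the second before onset is
excluded to absorb trigger jitter, and the search stops at the NH4 window
(the deprotonation plateau is not a stimulus response).  Responses are then
partitioned exhaustively: `pre_stimulus` (t < 0), `synchronized`
(0 ≤ t ≤ 1 s), `delayed` (t > 1 s), `nonresponsive` (no crossing).

Two robustness notes.  First, the 2×SD criterion as stated is sensitive:
with an estimated baseline SD, pure Gaussian noise produces sustained
false crossings in roughly a tenth of traces, which is why the sustain
count is exposed in the configuration.  The exactness guarantees in the
test suite are for the noiseless regime.  Second, with a noise-free
baseline the SD degenerates to zero; it is floored at 1e-9 of the trace's
dynamic range so that numerically negligible crosstalk cannot cross the
threshold.  Whether the criterion applies to raw or normalized traces is
an open choice; it is applied to normalized traces here, which makes the
threshold scale-free.

## Vesicle morphometry (STED)

A vesicle image is modelled as

    f(x, y) = A · exp[ −1/(2(1−cor²)) ( ((x−x0)/x_width)²
              + ((y−y0)/y_width)² − 2·cor·(x−x0)(y−y0)/(x_width·y_width) ) ]

optionally plus an additive offset.  With this parameterization the
intensity at `x0 ± x_width` (cor = 0) is `A·e^(−1/2)` ≈ 0.607 A — the width
parameters act as Gaussian sigmas even though the conventional name for
them is "half width at half maximum" (a Gaussian's true HWHM is
`√(2 ln 2) σ`).  The formula is taken as authoritative and reported sizes
follow it: `FWHM_axis = 2 · width · pixel_size`, mean half width
`(x_width + y_width)/2 · pixel_size`.

Fitting is bounded nonlinear least squares (trust-region reflective) from a
moments-based initializer (centroid, second central moments, mixed moment
clipped to ±0.95), with `|cor| ≤ 0.99`, widths ≥ 0.3 px, and tolerances of
1e−12 on step, cost and gradient within 200 iterations.  The additive
offset is fitted by default because real patches sit on background and
pinning it to zero biases widths; `fit_offset=False` reproduces the bare
six-parameter model.  Non-convergence is flagged and flagged fits are
refused by the size converter.

## Colocalization and mapping

Manders coefficients use the restricted-denominator form: `M1` is the
summed channel-A intensity on pixels where B exceeds its threshold divided
by the summed A intensity on pixels where A exceeds its own threshold
(symmetrically for `M2`), within the analysis ROI.  Thresholds default to 0
on background-subtracted images and are recorded in the result; an empty
denominator yields an explicitly undefined (None) coefficient rather than
a silent zero.

Synapse selection requires BOTH channels to exceed the local neurite
baseline (median of the surrounding neurite ROI, excluding a 3-px disk
around the punctum) by ≥ 1,000 AU, with the per-channel maxima co-located
within 2 px.  The per-channel AND reading of the dual-intensity criterion
is a deliberate interpretation; an additive reading would be weaker.

Line profiles follow the ImageJ wide-line convention: the path is resampled
at 1-px arclength spacing and each sample is the mean of `width` (default
3) bilinear samples spaced 1 px along the local normal.  Per-synapse
profiles are aligned by shifting the reference-channel maximum to the grid
centre (integer-sample shifts; overhanging samples are dropped from the
average) before computing the pointwise mean ± SEM.  The enrichment fold is
the mean of the averaged profile within ± `center_halfwidth` (default
0.5 µm) of the centre divided by the mean over the flank band (default
0.5–1.5 µm on both sides, boundary sample excluded from the flanks); it is
invariant to a common scale factor.

Synapse density is count per image area (µm²).  Distance to the nearest
soma uses the polygon boundary — the plasma membrane — with points inside a
soma at distance 0.

## Ratiometric calcium

`[Ca²⁺] = K_d · β · (R − R_min)/(R_max − R)` with the in-situ calibration
constants R_max = 3.73, R_min = 0.64, K_d = 350 nM, β = 6.73 as defaults.
Ratio pixels whose background-subtracted F380 falls below `min_f380` are
masked as invalid.  Ratios at or above R_max are masked (flag 2) rather
than capped — the relation diverges there and a capped value would be
fabricated; ratios below R_min clamp to 0 nM with a flag (1), since
negative concentrations are unphysical but the information is preserved.

## Synthetic scenes

The generators produce the statistical structure the analyses assume, with
complete ground truth, and are exactly invertible in the noiseless case:

* **TIRF movies** — immobile isotropic Gaussian spots (sigma 1.3 px,
  ≈ diffraction-limited at 160 nm pixels) on constant background;
  amplitudes jittered ±25% around 200 AU; single-exponential bleaching
  (default tau 300 s); full-fusion events remove the spot within one
  frame; kiss-and-run events render amplitude ×2 and width ×1.5 for 0.3 s
  before removal (the transient/cloud excursion is not quantified by any
  published measurement; these are declared generator defaults).  The
  default protocol is a 30-s 10-Hz pre-stimulus phase followed by a
  100-Hz stimulus phase, imaged at 10 Hz.
* **SypHy movies** — synapse puncta (placed ≥ 10 sigma apart — synapses on
  distinct neurites are sparse) whose amplitude is `surface_fraction ×
  pool` at rest, steps up at the programmed response time, and equals the
  full pool inside the NH4 window.
* **STED patches** — sums of the correlated-Gaussian surface above.
* **Fura-2 pairs** — the calcium relation inverted pixelwise
  (`R = (K_d β R_min + ca·R_max)/(K_d β + ca)`), which is below R_max for
  every finite concentration, so the noiseless round trip is exact.
* **Colocalization pairs** — binary supports with a controllable shared
  fraction; the true coefficients are computed from the constructed
  supports.

Noise (Gaussian read noise, optional Poisson) is added last and never
changes the stored truth; a fixed seed makes every generator bit-exact
reproducible.  The scenes deliberately omit moving vesicles, spatially
varying background, focus drift and detector artefacts, so passing tests
demonstrate the correctness of the analysis logic under the model's
assumptions — not performance on arbitrary real recordings.

## Problem sizes

The verification suite and the reproduction script use 200-frame 64×64
movies (10 spots, 3 events; 20 noise seeds at SNR 5), 120-frame 128×128
SypHy movies (20 synapses), 100 random Gaussian draws on 31×31 patches,
100 random 8×8 Manders pairs and 32×32 calcium maps — sizes at which every
recovery property is exercised end to end while the whole suite runs in
well under a minute.
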