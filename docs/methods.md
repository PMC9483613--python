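# Methods

`spiralmap` implements the computational side of a 1D spiral-micropattern
conduction assay for cardiomyocyte monolayers: a cell line is patterned into
a long, narrow spiral track so that an entire depolarization–repolarization
cycle fits into one microscope field of view, and conduction velocity (CV),
action potential duration (APD), and conduction wavelength (WL = CV × APD
or CV × ERP) are read out from voltage-dye fluorescence.  Because no public
recordings exist for this assay, a first-class synthetic-data module
generates every input with known ground truth; the analysis chain never
sees that ground truth.

## Spiral geometry

The track is an Archimedean spiral, r(θ) = r0 + p·θ/2π, with constant line
width d_l and inter-line gap d_s (pitch p = d_l + d_s, center to center).
Constant pitch matches a fabricated pattern with fixed line/gap widths.
Arc length is accumulated over chords sampled at ≤ 25 µm; at that step the
chord sum is within 10⁻⁵ (relative) of the exact integral, and halving the
step changes the total length by < 0.1%.

The default factory is calibrated to the fabricated device: d_l = 200 µm,
d_s = 400 µm, and the pair (r0, n_turns) solved once from the two published
path lengths — 5.5 cm for the base design and 7.9 cm after one additional
outer turn.  The solution is unique (two equations, two unknowns):
r0 = 1372.716859 µm, n_turns = 3.5763424.  These are frozen constants in
`geometry.py`.  The resulting bounding-box footprint is 44.8 mm², inside
the ~65 mm² field of a low-magnification objective.  Because "footprint" is
not a standardized enclosure, both an axis-aligned bounding box (default)
and an origin-centered enclosing circle are provided.

Self-intersection: adjacent turns of an Archimedean spiral are separated by
the normal distance p·cos φ with tan φ = b/r (b = p/2π), tightest at the
inner radius — about 1 µm under the nominal 600 µm pitch for the default
design.  `min_nonadjacent_separation` verifies this numerically.

## Synthetic recordings

Propagation is kinematic: a site at arc position x activates at
t_stim + x/cv and replays a fixed AP template, repeating at the pacing
cycle length (500 ms, i.e. 2 Hz pacing, which overrides intrinsic
automaticity and minimizes restitution effects).  A kinematic model was
chosen over a reaction–diffusion cable deliberately: it gives closed-form
ground truth for every estimator (activation times, wave extent
cv × APD80, peak-time differences), which is what a validation suite
needs.  The price is that the simulator cannot produce curvature effects,
source–sink mismatch, or rate-dependent block; parameter-recovery results
therefore validate the *measurement chain*, not cardiac dynamics.

The AP template has a linear upstroke (duration = APA / dV/dt_max) and a
logistic repolarization whose level crossings invert in closed form, so
nominal APD50/80/90 are exact.  Templates can be built from (APD50, APD90)
pairs or from a target APD80 with a fall width of 0.12 × APD80 — a
tail-to-duration ratio typical of optical APs.

Fluorescence follows F = F0·(1 + a·V_norm)·(1 − β·t) + ε with peak ΔF/F
a = 2% (typical of a fast voltage dye over a bright baseline), linear
photobleaching β = 0.5%/s, and Gaussian noise ε with σ = 0.5% of baseline
per pixel (shot-noise-like, proportional to the baseline).  Full-frame
movies run at 30 fps for 300 frames (10 s); line scans at 150 fps.  All
randomness flows through one `numpy` generator seeded from the config, so
identical configs are bit-identical.

Pattern defects mirror the two observed fabrication failure modes: a
`break` (discontinuity in the cell line) blocks conduction past its arc
position; a `bridge` (cells connecting adjacent turns) short-circuits two
arc positions, each end activating at the earlier of its own and its
partner's time and then acting as a secondary source.

Other arms: MEA field potentials are modelled as −dV/dt of the template on
an 8×8, 450 µm-pitch grid, either radially from the pacing corner (the
physical stimulation geometry) or as a plane wave; slice-style optical maps
spread an elliptical (anisotropic) or planar wave over a pixel grid at
1000 fps; the S1–S2 generator applies single-exponential APD/CV restitution
with a sharp diastolic-interval capture threshold, so the true ERP equals
steady-state APD + threshold.

## Spiral analysis chain

1. **Profile extraction** — mean intensity over a 10-pixel-wide
   cross-section normal to the centerline, sampled every 10 µm of arc, per
   frame (bilinear interpolation).
2. **Spatial filtering** — zero-phase (forward–backward) Butterworth
   low-pass, order 3, normalized cutoff 0.005 of the spatial Nyquist,
   applied along the arc axis per frame.  Zero-phase matters: a causal
   filter would displace wave edges.
3. **Normalization** — each (arc, frame) value is divided by that arc
   position's mean over all frames (cancelling the static illumination/dye
   pattern), then a per-arc first-order baseline fitted on diastolic
   frames only is divided out (removing photobleaching drift — with a 2%
   signal over a bright baseline, a 0.5%/s drift is the same order as the
   signal), the baseline of 1 is subtracted, and the residual is rescaled
   to unit maximum ("amplified").  All downstream measurements are
   threshold-relative, so the amplification factor is immaterial (tested).
   The diastolic-frame selection is adaptive: samples more than 30% of the
   residual span above the row minimum are excluded from the fit, keeping
   15–50% of frames, which stays on the diastolic plateau even when APD
   approaches half the pacing cycle.
4. **Wavelength measurement** — per frame, the wave is the widest
   contiguous arc interval where the signal exceeds 20% of that frame's
   maximum, i.e. the extent at 80% repolarization, with sub-sample edges
   by linear interpolation.  This is the same 80%-repolarization convention
   as APD80, so for a kinematic wave the extent equals cv × APD80 and the
   measured WL is directly comparable to the calculated one.  Only
   *complete* waves (both edges ≥ 1 arc step inside the path) count, and a
   mean is reported only when ≥ 10 qualify; otherwise the measured WL is
   reported absent with a reason — which is the physically expected outcome
   whenever cv × APD80 exceeds the 5.5 cm path.
5. **Line-scan endpoints** — APD80 per beat as the time between the
   upstroke and repolarization crossings of baseline + 20% of amplitude
   (sub-sample interpolated, beats averaged); travel time as the mean
   peak-time difference between the electrode-region and terminal-region
   traces (parabolic sub-sample peak refinement); CV = separation / travel
   time.  Traces are smoothed with a moving median (5 samples) plus a
   zero-phase 40 Hz low-pass — a documented, pluggable stand-in for the
   unspecified smoothing of the original pipeline — and detrended with the
   same robust diastolic first-order fit.  The per-beat diastolic baseline
   is the 10th percentile of the preceding inter-peak segment: a median
   would land on the repolarization tail when APD approaches half the
   cycle length.

Numerical behavior worth knowing: the spatial low-pass widens the measured
extent by ~0.05–0.1 cm (an additive, nearly constant edge bias that moves
the regression intercept, not the slope); line-scan regions span only
~400 µm of arc (a scan line crossing the narrow track), keeping activation
spread within a region below one sample; recovery across cv 15–45 cm/s and
APD80 150–300 ms at default noise is within ~3.5% (CV) and ~5 ms (APD80).

## Patch-clamp features and classification

Features per AP: MDP (minimum between beats), APA (peak − MDP), dV/dt_max
(maximum 4-sample secant slope of the 5-sample-smoothed upstroke — a secant
cannot overshoot at the upstroke corner, and the smoothing keeps
single-sample noise out of the derivative), and APD50/APD90 measured from
the rising-phase crossing to the falling-phase crossing of each
repolarization level.  Multi-beat traces are averaged.

Two published rule sets classify nodal / atrial / ventricular phenotypes
and genuinely disagree; both are implemented behind a flag.  The default
"text" rules: nodal = APA < 100 mV, MDP > −50 mV, dV/dt_max < 5 V/s;
working myocytes (MDP < −55 mV, dV/dt_max > 5 V/s) split into ventricular
(APD90 > 400 ms OR APD90/APD50 < 1.2) and atrial (APD90 < 300 ms OR
ratio > 1.2).  The "caption" rules require MDP < −60 mV and join the
criteria conjunctively.  A cell satisfying both the atrial and ventricular
disjuncts, or falling in the MDP gap between the nodal and working-myocyte
cutoffs, is returned `unclassified` with a rule trace — the gaps are a
property of the published rules and are surfaced, never tie-broken.

## 2D maps

Slice stacks are conditioned with a 150 Hz zero-phase temporal low-pass
(configurable 100–150 Hz), a 7×7 boxcar spatial average, per-pixel min–max
normalization to [0, 1], and per-pixel first-order drift removal fitted on
diastolic frames (a plain least-squares detrend would tilt on the AP hump
and drag the trace below baseline).  Activation is the interpolated first
50%-upstroke crossing; APD90 is measured per pixel with the below-baseline
motion-artifact rule (trace dipping more than 10% of its amplitude below
the diastolic baseline → site invalid).  The conditioning chain carries a
few-ms systematic on the slow APD90 tail (≈3 ms at 1 kHz); this is a
property of the published preprocessing, not of the estimator.

Longitudinal/transverse CV uses a standard plane-fit velocity field (a
deliberate, labelled substitute for specialized conduction-analysis
software): least-squares planes of activation time over sliding 7×7
neighbourhoods give local velocity vectors (speed = 1/|∇t|), vectors are
binned by direction (10° bins, mod 180°), and the maximum and minimum
bin-median speeds are the longitudinal and transverse CV.  Bin medians are
robust to the near-source curvature bias of plane fits; on 80×80 grids the
51/28 cm/s anisotropic benchmark is recovered within ~3%.

MEA activation is the time of the maximal negative slope of each field
potential (the standard convention, sub-sample refined).  The array CV is
the mean of the horizontal, vertical, and diagonal vectors from the
stimulation corner (electrode-path distance / activation-time difference);
vectors with missing or non-positive delays are dropped with a warning.
This three-vector average equals the true speed only for a wave expanding
from the paced corner, which is why the simulator's radial mode — not the
planar one — is the matching validation geometry.

## EP endpoints

ERP is read from a decremental S1–S2 capture scan as the longest coupling
interval that fails to capture (the interval at loss of capture); the
"last captured interval" convention is available via a flag, the two
differing by exactly one 10 ms decrement.  The scan must be monotone —
capture regained after loss is a protocol violation, not data.  For any
monotone capture function the estimate is within one decrement of the true
boundary.  Catheter CV divides the 20 mm electrode span by the conduction
time.  Cohort tables report mean ± SEM per (group, side, endpoint), with
each record's WL computed before averaging (mean of products — the product
of means differs for heterogeneous records and is not what per-subject
analysis does).  No restitution correction is applied across drive cycle
lengths (400–1000 ms), mirroring the empirical rate-independence of these
endpoints in that range; inferential statistics are out of scope.

## What the synthetic tests do and do not show

Passing parameter recovery shows the measurement chain is unbiased and
precise *under the generator's assumptions*: constant-speed kinematic
waves, spatially uniform APD, linear bleaching, Gaussian noise, and an AP
template with a single repolarization time scale.  Real recordings add
motion artifacts, heterogeneous dye loading, wavefront curvature and rate
adaptation, none of which are emulated; results on real data depend on
those factors and the synthetic suite cannot certify them.

## Problem sizes

Default problem sizes were chosen to keep the full loop comfortably
interactive: 300-frame movies at 40 µm/px (~200×200 images), 10 µm arc
sampling (5 500 profile points), 80×80 slice grids at 1 kHz, 64-electrode
MEA traces at 5 kHz.  The wavelength-validation batch uses ~35 recordings
spanning cv 15–25 cm/s and APD80 150–220 ms, the span over which complete
waves fit the 5.5 cm path.
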