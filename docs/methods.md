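# Methods

## Measurement model

All quantities derive from 1D fluorescence intensity profiles sampled along
polyline ROIs on a maximum intensity projection of a confocal z-stack.
Profiles are sampled at 0.5-pixel arc steps by bilinear interpolation, each
sample averaged across an odd `sampling_width` (default 3 px) perpendicular
to the path; sub-pixel sampling keeps peak areas stable against vertex
placement.

**Background.** The paper-style workflow subtracts a scalar background. The
default estimator is the 5th percentile of the ROI's own raw profile —
self-contained and robust to field inhomogeneity — which requires the
profile to contain genuine background samples; the synthetic dendrite ROI
therefore ends in a short (3 μm) perpendicular spur into background. An
explicit `roi_mean` estimator accepts a level measured from a separate
background ROI. Corrected values are floored at zero.

**Dendrite normalization.** The reference is the mean (optionally median) of
background-corrected values over a user-designated adjacent-dendrite
segment of the same profile; dividing by it puts the shaft at 1 "normalized
dendrite unit" and cancels acquisition gain, which is the stated purpose of
the step. Whether the original workflow used a mean or a local reference is
not determinable; the mean is the default and the only mode used in tests.

**Spine detection.** Threshold semantics: "50% brighter than the adjacent
dendrite" reads as normalized apex ≥ 1.5, the only self-consistent
interpretation on a dendrite-normalized profile. One spine per
supra-threshold excursion (jagged, noise-split apices never count twice);
peak bounds are the nearest crossings of the dendrite baseline (normalized
value 1), clipped at the valley between neighboring peaks sharing one
above-baseline excursion. Spine size integrates `max(normalized − 1, 0)`
trapezoidally between the bounds — the baseline is the dendrite level, not
the detection threshold, since the size proxy is the whole excursion above
the dendrite. No smoothing is applied by default. No outlier exclusion is
applied to sizes. Density divides the peak count by the traced dendrite
length; when an ROI carries a recorded traced length (as generated ROIs do,
excluding the background spur), that length is the denominator, otherwise
the polyline arc length is used.

**Microglia.** The trace is normalized to background by division
(background ≡ 1), not to the dendrite. Soma size = maximum normalized value
within the delineated soma span × span width in μm (span width rather than
FWHM, matching "peak × width"). The soma span is an input — delineating
"the portion of the trace corresponding to the soma" is a manual step — and
must cover the soma's blurred shoulder; the span is excluded (masked to
baseline) before process detection so a process adjacent to the cell body is
not swallowed by the soma's own excursion. Processes are peaks ≥ 1.25 ×
background outside the span; process area sums per-peak AUC above 1;
process perimeter counts profile samples (in pixels) covered by any peak's
bounds, overlaps merged, divided by the pixel/μm scale.

**Percent area.** A plain thresholded pixel count; the threshold is an
explicit argument (no automatic Otsu default) because the original tool's
settings are unpublished.

**Statistics.** Mean ± SEM (sd with n−1 over √n). Two groups: unpaired
pooled-variance t test (degenerate zero-variance equal-mean input reports
t = 0, p = 1). Three or more: one-way ANOVA with Tukey HSD; the HSD is
computed in-package (Tukey–Kramer q against the studentized-range
distribution) so an independent library implementation can cross-check it.
Factorial designs: fixed-effects two-way ANOVA with type-II sums of squares
and Tukey or Holm–Šidák pairwise correction — the original analyses mention
repeated measures, but the repeated factor (slices per animal) is not
specified anywhere, so per-unit fixed-effects ANOVA is the deliberate,
documented simplification; no mixed-effects modelling is attempted.
Normality: Lilliefors KS against a fitted Normal (no a-priori parameters
exist to fix), p from the Monte-Carlo table. α = 0.05 throughout, starred
at 0.05/0.01/0.001.

## Synthetic data

The generators emulate three image classes with exact ground truth.

**Dendrites.** A Gaussian-ridge shaft (FWHM 1 μm, 100 a.u. on a 10 a.u.
background) runs horizontally; spines are isotropic 2D Gaussian heads
(FWHM 0.7 μm) displaced laterally by shaft_width/2 + 0.2 μm neck. The ROI
runs along the line of spine-head centers for the dendrite's length — so the
blurred shaft flank along that line is the "adjacent dendrite" the analyst
normalizes to, and the normalized baseline between spines sits at 1 — then
turns into background for the percentile estimator. Spine amplitudes are
drawn N(2.0, 0.4) in units relative to the local dendrite level and
analytically compensated for PSF and sampling-width attenuation, so the
noiseless normalized apex is 1 + amplitude (verified to ~1% in tests; the
shaft extends 1 μm beyond the ROI so the reference segment never sees the
end taper). Spine count defaults to the deterministic round(density ×
length) with uniform placement under a 1.5 μm minimum spacing (a Poisson
count mode exists); density defaults to 0.5 spines/μm — resolvable at this
optical scale — on segments of 20 μm, varied ±5 μm per image in the
condition pipeline as traced segments vary in practice.

**Microglia.** A flat-topped super-Gaussian soma ellipse (10 μm long axis,
100 a.u.) on a 20 a.u. background; each process is a narrow elongated arm
(FWHM 1 μm wide, ~12 μm long) crossing the measurement line exactly once at
a jittered offset outside the soma span — a stylized stand-in for the one
crossing per process the line method assumes. Placement is slotted with
non-overlap margins; requesting more processes than placeable raises an
error.

**Staining fields.** A smoothed random field thresholded at the exact order
statistic marking round(fraction × H × W) pixels positive, then passed
through the noise model without PSF blur (blur would redistribute the
positive-pixel count that constitutes the ground truth).

**Acquisition.** Isotropic Gaussian PSF; z-stacks replicate the scene with
out-of-focus planes dimmed (×0.6 per plane) and extra-blurred; Poisson shot
noise on photon-scaled intensity plus additive Gaussian read noise,
quantized to 8/16 bits. Defaults: 0.1 μm/px, PSF σ 0.15 μm, 5 photons/a.u.
for spines; 0.3 μm/px, PSF σ 0.3 μm, 20 photons/a.u. for whole-cell
microglia fields (larger fields, longer dwell). The paper's pixel sizes are
not published; these are configurable choices at realistic confocal scales.

**Condition presets.** WT-vehicle is the unit baseline. L-AAA multiplies
spine density by 0.67 in both genotypes; spine size by 0.53 on the 5XFAD
background only (5XFAD-vehicle itself carries a 0.8 size factor vs WT —
direction reported, magnitude a modelling choice). Microglia under L-AAA:
process factor 0.6, soma factor 1.25 (5XFAD: 0.85 / 1.1) — directions as
observed, magnitudes chosen once as plausible since no percentages are
printed for them.

### What the synthetics do and do not show

The generators provide straight dendrites, well-separated Gaussian spines in
a single focal plane, processes that cross the measurement line exactly
once, and stationary backgrounds. Passing recovery tests therefore
demonstrates that the *measurement chain* is faithful to its definition and
robust at realistic SNR — not that the method handles crossing neurites,
out-of-plane spines, curved processes crossed twice or zero times, or
spatially varying background. Those are limitations of the 1D-profile
method itself, reproduced here by design (no skeletonization or Sholl
analysis is attempted, and ROIs are inputs, never proposed automatically).

## Numerical choices

- Profile step 0.5 px; positions in μm from the first vertex.
- Peak bounds on sampled indices; areas by `np.trapezoid` on the clipped
  excess; a single-sample spike has zero area.
- Ties inside a supra-threshold run resolve to the first maximal sample.
- Degenerate inputs raise: empty stacks, out-of-bounds ROI vertices (first
  offending vertex named), non-positive dendrite reference, empty soma
  span, infeasible spine packing, unplaceable process counts.
- Seeds: every generator takes an explicit integer seed; the pipeline
  derives per-image seeds from the master seed via `SeedSequence`, keeping
  them below 2^31. Two runs with equal configs are byte-identical,
  including CSV outputs.

## Known measurement biases (quantified by the test-suite conditions)

- AUC spine size is measured between noisy baseline crossings: rectified
  noise adds a small positive, amplitude-independent offset, and densely
  packed spines lose tail area to valley clipping. Net effect at default
  SNR: recovered size reductions run ~2–4 percentage points above the
  programmed ratio; density reductions ~1 point below (split/false peaks
  weigh more in sparse groups).
- The 5th-percentile background estimator sits ~1–2 a.u. below the true
  background mean under noise, shrinking normalized amplitudes by a few
  percent symmetrically across groups (ratio-neutral).
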