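# Methods

This note records the models implemented in `nodulemap`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data can and cannot say about a physical experiment.

## Phantom model

A phantom is a rectangular block (default 100 × 60 × 15 mm; origin at one
corner, x along the 100 mm edge, z downward from the indented surface, all
intervals closed) of a soft matrix with spherical inclusions. Materials are
described by four positive constants: acoustic impedance (MRayl), speed of
sound (m/s), indentation stiffness of the pure material (N/mm), and one-way
attenuation (dB/cm, with the reference frequency recorded next to it). Two
recipes are built in: a healthy-tissue mimic (1.59 MRayl, 1457 m/s,
0.33 N/mm) and a tumor mimic (1.92 MRayl, 1534 m/s, 4.6 N/mm), both at
1.25 dB/cm @ 16 MHz.

The reference builder places eight tumor-material spheres, two per diameter
in {3, 6, 9, 12} mm, by seeded rejection sampling under two constraints:
≥ 10 mm planar surface-to-surface separation and ≥ 5 mm clearance from the
lateral faces. Sphere centers sit at mid-thickness (z = 7.5 mm); the
`deep_small` option moves the 3 and 6 mm centers to z = 10 mm. Exact
inclusion positions and depths are not identifiable from a bench photograph
of such a phantom, so they are free, seed-generated quantities here; the
experiment-level default buries the small inclusions because a deep small
nodule under a soft bulk is precisely the case palpation struggles with,
and the evaluation is designed to exhibit that failure mode.

**Effective stiffness.** No closed-form contact model exists for a rigid
flat punch over a layered block, so the local stiffness is homogenized as
two springs in series along the indentation axis: with block thickness `T`,
maximum inclusion chord `t` under the probe footprint, matrix stiffness
`k_m` and inclusion stiffness `k_i`,

    k_eff = 1 / ((T − t)/(T·k_m) + t/(T·k_i)).

This recovers both homogeneous limits exactly, is strictly increasing in
the chord, and stays within `[k_m, k_i]`. Note the model depends on the
chord only — a 3 mm sphere yields `k_eff ≈ 0.41 N/mm` against a 0.33 N/mm
matrix regardless of depth, which is what makes small nodules nearly
invisible to palpation here. The probe footprint is a 3 mm disc sampled on
a 0.5 mm sub-grid; the maximum chord over the footprint is used because a
rigid probe face is dominated by the stiffest column underneath it.

**Reflection coefficient.** `((Z₂−Z₁)/(Z₂+Z₁))²` at a planar interface;
for the two recipes this is ≈ 0.0088, i.e. < 1 % of the incident intensity.
This motivates the reflectometric design: the method watches the strong
echo from the steel plate under the phantom, not the faint direct
reflection off an inclusion.

## Scan simulator

The simulator replaces the motorized platform and reproduces its
acquisition parameters as defaults: 0.5 mm/s indentation, 0.2 N trigger,
2 mm grid step, 3 mm probe, 16 MHz center frequency with 0.25 fractional
bandwidth at −6 dB, 1.6 GHz sampling, 0.004 N load-cell resolution (used as
the force-noise standard deviation).

**Indentation.** Linear-elastic with a sharp contact point at a fixed
1.0 mm approach depth: zero force (noise only) before contact, then
`Fz = k_eff·(Z − Z_contact)` plus Gaussian noise, sampled at 500 Hz (1 µm
per sample at 0.5 mm/s), ending at the first sample at or above the
trigger. The stiffness feature is a secant slope, so any monotone force law
would serve; the linear one makes recovery exact, which turns the
estimator's correctness into a sharp test.

**A-scan.** A cosine tone burst under a Gaussian envelope whose −6 dB
spectral full width equals `0.25 × 16 MHz`, centred at the two-way time of
flight through the layered column ((T − t) of matrix at its speed, chord t
at the inclusion's; ≈ 20.59 µs for the homogeneous 15 mm block). The peak
amplitude is the pulse amplitude attenuated by the two-way path,
`10^(−2·α·T/20)` with α in dB/cm scaled linearly with frequency from its
reference. Over an inclusion the amplitude drops by a further factor
`(1 − drop · t/d)` where `d` is the intersected inclusion's diameter, so
the drop reaches its configured maximum (default `drop = 0.5`) at the
centre of *every* inclusion regardless of size — the size-independent echo
contrast that makes the ultrasound channel sensitive even to 3 mm nodules.
The chord is evaluated over the same 3 mm probe footprint as the stiffness,
which slightly enlarges inclusions in the CIA map and produces the
characteristic boundary false positives. Reported bench observations of
the echo drop over vs. outside inclusions are ambiguous between ~10 % and
~60 %, so the factor is a parameter rather than a constant. Inclusions
flagged as containing an air bubble have their echo restored toward the
inclusion-free amplitude in proportion to `bubble_fraction` (bubbles make a
nodule look acoustically healthy; they do not affect the stiffness
channel). Record length defaults to 0–30 µs, covering the echo with margin.
Additive white noise has standard deviation `us_noise_sd` (default 0.02)
relative to the inclusion-free echo peak.

**Randomness.** One master seed. Per-point noise substreams derive from a
seed sequence over `(seed, x·1000, y·1000)` with coordinates in µm, so
reordering the grid leaves every point's noise unchanged.

**Scene rendering.** The camera view is synthesized as a low-frequency
textured background plus a brighter rotated rectangle for the phantom,
rasterized with 4× supersampling so edges carry sub-pixel coverage
information. Default scale is 0.5 mm/pixel.

## Vision

Background subtraction takes `|sample − background|`, thresholds at a
fraction (default 0.1) of the difference's dynamic range (scale-free on
synthetic images), fills holes and keeps the largest connected component.
Orientation is the principal-axis angle from second-order mask moments,
reported in (−90°, 90°]; normalization rotates the continuous coverage
image (bilinear) about the centroid by that angle and re-thresholds, which
keeps the aligned outline sub-pixel accurate. Poses are assumed within
±90° so alignment involves no 180° flip ambiguity.

The indentation lattice is laid over the mask bounding box at the grid step
(2 mm), anchored at the box's minimum corner, row-major. A point is kept
when it lies on the mask at least `margin` from the border (default 1.5 mm,
the probe radius, so the probe never overhangs); the distance test allows
half a pixel of slack to absorb rasterization. Because both the grid origin
and the lattice anchor are the bounding-box corner, small rasterization
shifts cancel, and a rotated-then-normalized scene reproduces the
aligned-pose grid point-for-point.

## Features

Stiffness: contact is the first sample at or above
`max(0.02 N, 5 × force-noise sd)` whose successor also stays above 80 % of
that threshold (two-sample confirmation rejects isolated noise spikes well
below the 0.2 N trigger); the secant slope runs from there to the trigger
sample. CIA: energies are summed over the full recorded window, no gating.
The reference A-scan is the maximum-energy one — under the reflectometric
model inclusions only remove echo energy, so the strongest echo is the best
inclusion-free proxy when ground truth is unknown; an explicit reference
index can be supplied instead.

## Classification and fusion

Fuzzy C-means with two clusters, fuzzifier m = 2, membership tolerance
1e-5, ≤ 300 iterations, seeded random membership initialization — standard
values, as the bench protocol fixes none. The membership update uses
distance ratios to the nearest centroid, which is overflow-safe even for
degenerate spreads; points coincident with a centroid get full membership
there. Clustering runs per phantom and per feature map (each replica was an
independent scan; the two sensors are fused *after* labeling, which is what
gives AND/OR their meaning). The larger-centroid cluster is tumor, exact
membership ties go healthy, and a map whose values are all identical (e.g.
a noiseless homogeneous block) raises a degenerate-clustering condition
that the pipeline converts into an all-healthy map plus a warning.

AND/OR fusion is point-wise boolean on labels (min/max on memberships). By
construction the false-negative set of OR is the intersection of the input
FN sets, and the false-positive set of AND is the intersection of the input
FP sets; the test suite asserts these as exact set identities.

## Evaluation

Truth is planar: a grid point is tumor when it lies inside any inclusion's
projected circle, boundary inclusive, ignoring depth — this is what makes
deep small nodules *count against* the stiffness channel. Rates are
class-conditional (TP% + FN% = 100 over truth-tumor points, TN% + FP% = 100
over truth-healthy points); accuracy and misclassification are fractions of
all points. Replicate phantoms are reported individually and pooled by
summing counts (pooling by counts and recomputing rates is asserted
consistent in the tests; per-phantom rate averaging is available from the
per-phantom summaries).

## Problem sizes and defaults of the shipped experiment

Seven replicate phantoms, ~1 420 grid points each (2 mm step, 1.5 mm
margin), one indentation trace (~1 600–2 600 samples at 500 Hz) and one
A-scan (48 001 samples at 1.6 GHz) per point. Scans are processed one
phantom at a time and raw signals are only written to disk on request,
since the waveform arrays dominate memory and storage.

## Known limitations

* The stiffness homogenization ignores depth, lateral confinement and
  contact mechanics (no Hertz/flat-punch theory, no viscoelasticity).
* The acoustic model has no beam diffraction, speckle, reverberation or
  frequency-dependent pulse distortion; inclusion echo contrast is a single
  configurable factor, not derived from the inclusion's acoustics.
* The camera model renders ideal high-contrast scenes; segmentation
  robustness to lighting, shadows or specular highlights is untested.
* Consequently, passing tests demonstrate the correctness of the estimators,
  the clustering, the fusion logic and the evaluation arithmetic under the
  stated models — not the detection performance attainable on biological
  tissue.
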