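# Methods

This note records the models, parameter choices, and numerical decisions
behind `panopaus`, and what the synthetic tests do and do not establish
about real acquisitions.

## Scan kinematics and planning

The scotch-yoke mechanism converts uniform motor rotation into
reciprocating elevational motion.  With arm length *R* and motor angle
θ, the probe's elevational position is `y(θ) = R (cos θ_start − cos θ)`.
The motor angle is advanced in `frames_per_scan − 1` uniform increments
spanning `[θ_start, θ_end]` — an interval convention chosen so the first
and last frames land exactly on the configured scan angles and the step
sequence telescopes exactly to the full scan range.  With the default
scanner (R = 15 mm, 32°–145°, 83 frames) the steps range from 0.19 to
0.36 mm, below half the 1 mm elevation beam-width, which is the spatial
anti-aliasing condition `check_elevation_sampling` enforces (strict
inequality).

Scan timing is `T_scan = T_frame × p × q` (p frames, q wavelengths; the
motor turns q× slower so the step size is wavelength-count-invariant).
`plan_timing` also accepts a measured per-scan override for planning
with realized rather than nominal durations, since mechanical scan
periods in practice differ by ~0.5% from the nominal product.

The laser-safety check uses the ANSI pulsed skin maximum permissible
exposure, `20 × 10^(0.002 (λ − 700)) mJ/cm²`, valid for 700–1050 nm only;
out-of-band wavelengths are rejected rather than extrapolated.

## Synthetic acquisition model

The simulator is a single-scattering, straight-ray PA forward model, not
a wave solver.  Per absorber point source the received trace at each
element is a band-limited pulse — Gaussian envelope at the 8.5 MHz array
centre frequency with σ set from the −6 dB fractional bandwidth (62%) —
delayed by the one-way time of flight, scaled by

* absorber strength and, for hemoglobin-bearing absorbers, the molar
  extinction mixture `(1 − sO₂) ε_Hb(λ) + sO₂ ε_HbO₂(λ)` (same table the
  unmixing stage uses, so end-to-end recovery tests close the loop);
* depth-dependent optical fluence `exp(−μ_eff (z − z_skin))`;
* 1/r geometric spreading;
* a Gaussian elevation sensitivity whose FWHM is the stated 1 mm
  elevation beam-width.

Laser pulse-energy jitter multiplies each frame by `1 + jitter·N(0,1)`
and is recorded per frame, which is what the calibration stage divides
out.  White channel noise is added last.  All randomness flows through
one seeded generator.

Geometries: *threads* are thin (90 µm) wavelength-independent lines
running along the elevation axis, so each cross-sectional frame sees
them as dots (the configuration used to measure axial/lateral PSF widths
and depth-dependent SNR); *vessels* are cylinders along elevation with an
assigned sO₂.  Vessel phantoms embed the cylinders in a frozen 3D field
of weak wavelength-independent scatterers (defaults: 50 000 scatterers,
strength 0.04 vs. vessel strength 25) emulating diffuse tissue
background ~25 dB below the vessels; the field is three-dimensional so
its speckle decorrelates along the scan direction as tissue speckle
does.  This background is what makes per-depth fluence normalization
estimable — in a scene with no background signal that stage has nothing
meaningful to divide by.

Default μ_eff is 0.18 mm⁻¹, chosen once so that the thread phantom's
ApSNR decays ≈1.2 dB/mm over the 12–24 mm band after the depth-growing
receive aperture partially offsets attenuation and spreading.

The US simulator is phenomenological: Rayleigh speckle, a bright Gaussian
skin line at the configured depth, and echogenic blobs/rings at absorber
boundaries.  It exists to give the skin-detection stage a realistic
contour source, nothing more.

What the synthetic model omits: acoustic heterogeneity and reflection
artifacts, frequency-dependent acoustic attenuation, shadowing beneath
strong absorbers, wavelength-dependent fluence spectra (μ_eff is shared
across wavelengths), speckle from coherent tissue microstructure in PA,
and probe/tissue motion.  Tests passing on this model therefore
establish the correctness of the processing algebra (delays, stacking,
interpolation, unmixing, projection, blending) and plausible parameter
recovery — not performance on real tissue.

## Image formation

PA frames use one-way delays (|pixel − element|/c), US two-way (plane-
wave transmit depth + return path).  The image grid follows the US
convention: axial pitch c/(2 f_s) = 19.25 µm — which is also the pixel
bookkeeping behind the 40-pixel (0.77 mm) skin-removal offset — and
lateral pitch equal to the 0.3 mm element pitch.  Delays are linearly
interpolated between RF samples; a ±30° acceptance angle bounds the
receive aperture; no receive apodization is applied.  DAS sums delayed
samples; DMAS accumulates signed-square-root pairwise products through
the identity Σ_{i<j} y_i y_j = ((Σy)² − Σy²)/2, keeping it O(N) per
pixel.  Envelope detection is the analytic-signal magnitude along the
axial axis.

Localization accuracy: point targets beamform to within one pixel of
their true position when they sit on a lateral pixel centre.  Coherent
summation along a line target skews its envelope peak ~0.1% of depth
deeper — up to about 1.3 axial pixels at 24 mm — so depth checks on
thread phantoms use a two-pixel tolerance.

## Volume assembly

Raw stacks carry the non-uniform scotch-yoke elevations explicitly;
`resample_uniform` interpolates linearly onto an arithmetic grid
(default 0.059 mm, giving 424 planes over a 25 mm scan).  Linear
interpolation is monotone, conservative (volume integral preserved to
<1% for band-limited fields), and exactly reproduces affine fields —
all of which are tested.  The 0.059 mm default is configurable; it is
not an integer divisor of the scan range and is treated as an opaque
processing constant.

Skin detection thresholds each US column at 50% of its maximum and takes
the first crossing, then median-smooths the index map over an 11×11
column window; columns with no signal inherit the median of valid
columns.  Skin removal zeroes everything above contour + offset
(default 40 pixels = 0.77 mm).

Fluence compensation divides each cross-section by a per-depth-row
background level, rows indexed relative to the skin contour.  The row
level is the lower quartile of sub-threshold voxels (threshold 10% of
the frame maximum) pooled laterally.  The lower quartile, not the
median, is used because sidelobe clutter around strong absorbers
inflates the upper part of the in-row amplitude distribution — and does
so wavelength-dependently, which would otherwise tilt unmixed spectra;
the clutter-free columns populate the lower quartile.  Rows without
background voxels inherit the nearest valid row's level; a frame that is
entirely background self-normalizes on all positive voxels.  An optional
``profile="exponential"`` mode replaces the row levels with a robust
(Theil–Sen) log-linear fit, appropriate when clutter-contaminated depth
bands are a small minority of the rows.

Even with the quartile estimator, per-wavelength background division in
scenes whose diffuse background is comparable to vessel sidelobe clutter
tilts unmixed spectra by a few percent at the vessels' own depth —
high-saturation vessels then read a few points low.  This is a known
limitation of depth-wise per-wavelength background normalization in
sparse scenes, not of the implementation; the end-to-end tests therefore
read the artery ROI from un-normalized volumes (the test phantom's
vessels share one depth, making depth equalization a no-op there) while
the vein is read through the full normalizing pipeline.

## Spectral unmixing

Per voxel, `P(λ) = ε_Hb(λ) C_Hb + ε_HbO₂(λ) C_HbO₂` is solved by
unconstrained least squares (pseudo-inverse of the n_λ×2 extinction
matrix), then negative concentrations are clamped to zero — the
coordinate-wise projection onto the non-negative orthant, matching the
convention of truncating overfitting artifacts rather than running a
constrained solver.  The shipped extinction table holds approximate
literature molar extinction coefficients at 756 nm (Hb-dominant), 797 nm
(isosbestic), 866 nm (HbO₂-dominant) and is config-replaceable; only its
dominance/isosbestic structure is relied on.

sO₂ = C_HbO₂/(C_Hb + C_HbO₂) with NaN marking voxels where both
concentrations are zero; NaNs are excluded from every statistic and
never collapse to 0 or 1.  The sO₂ MAP projects, per (x, y) column, the
sO₂ value at the axial argmax of C_HbO₂ (ties to the shallowest voxel).
Median filtering acts in the elevation–lateral plane with metric window
sizes, `round(size/spacing)` forced to the nearest odd count (4 mm at
0.059 mm spacing → 67 planes); it is applied to the per-wavelength
volumes before unmixing and optionally to the projected map after, where
NaN pixels are nearest-neighbour-filled for the filter pass and then
restored.  ROI statistics rasterize per-frame polygons (plain-text
format, vertices in mm) into a volumetric mask.

## Stitching and rendering

Poses are 3 translations + 3 rotations, intrinsic z–y–x Euler angles
about the volume centre (the convention is stored in every serialized
pose).  `apply_pose` resamples trilinearly onto a target grid via the
inverse mapping; `union_extent` pads the transformed bounding box to
whole voxels at the finest input spacing — the panoramic analogue of
zero-padding each volume to the panorama size.  Blending weights ramp
from each volume's faces (linear or Hann window; default linear over the
full half-extent, i.e. a full-width window) and are normalized to sum to
one wherever coverage exists, floored at 10⁻⁶ inside a volume's
footprint so single-coverage voxels always return their own data
exactly.  Pose estimation itself is out of scope: poses are numeric
inputs.

Rendering: MAP/MIP is the per-column axial maximum; depth encoding
returns the depth (mm) of that maximum where it exceeds a threshold;
the cumulative MAP reproduces the online preview, growing column by
column as frames stream in, with the final image equal to the
full-stack projection exactly.

## Quantification

pSNR is `20 log₁₀(peak over the signal box / std over the noise box)` —
the prevailing phantom-study convention; boxes are explicit inputs so
the convention is auditable.  ApSNR averages per-frame pSNRs over all
frames (and repeat volumes).  FWHM locates the two half-maximum
crossings of a single-peaked profile by sub-sample linear interpolation
and rejects multi-modal profiles.  The depth slope is the magnitude of
the ordinary least-squares ApSNR-vs-depth slope; on the three printed
thread pairs it evaluates to 1.208 dB/mm.  Absolute dB and µm values are
hardware-dependent and are asserted only as trends on synthetic data.

## Problem sizes used in tests

The suite runs everything at reduced scale chosen for thorough coverage
per CPU-second: beamforming oracles on a 32-element array, assembly and
recovery pipelines on 5–11-frame scans with 320–704-sample RF records,
and one full-scale 83-frame single-wavelength scan exercised end to end.
The three-wavelength vessel-recovery test uses 11 frames at 320 samples,
at which scale both assigned saturations are recovered within 0.03.

## Container and exports

One HDF5 container per scan position: `/pa/<wavelength>` and `/us`
volume groups (data, spacings, origin, pose, append-only provenance
strings, optional explicit elevation coordinates) and `/rf/<wavelength>`
frame datasets with per-frame pulse energy and elevation.  A format
name/version attribute guards against foreign files.  TIFF export
quantizes to 16 bits with an offset/scale JSON sidecar (values
round-trip to within one quantization step); NIfTI export carries the
voxel spacings and never resamples anisotropic data.
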