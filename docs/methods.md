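# Methods

## Geometry and conventions

World axes are lateral = +x, elevational = +y, axial (depth) = +z, with the
rotation axis along +z through the array centre and angles positive
counter-clockwise seen from the probe.  Angles are degrees at every public
interface.  All lengths are millimetres; indices are 0-based; voxel centres
of reconstruction grids sit at `origin + (index + 0.5) · spacing`.

A beamformed slice is stored on the acquisition grid: lateral spacing
equals the element pitch (`sle = p`), axial spacing follows from the sound
speed and sampling rate (`sa = c·10³ / (2 f_s)`, 0.018625 mm for the
reference probe), and the lateral pixel count equals the element count.
Slices span the **full** lateral aperture with a signed lateral coordinate
that is zero on the rotation axis.  Each physical acquisition images both
lateral half-planes at once, so a 0–179° sweep of full-width slices covers
the entire disc; formulations that split the array into halves index the
same data as 360 half-slices.  The axial sample count is taken from the
recorded data, not from the probe description.

The reference probe (package defaults) is a 68-element, 10 MHz linear array
with 0.2 mm pitch, 8 mm element height and a fixed elevational focus at
45 mm, sampled at 40 MHz in 1490 m/s medium.  Its elevational f-number is
`F/h = 5.625`; this value seeds every f-number default in the package.

## Virtual-source forward model

The simulator stands in for a full wave simulation at desk scale and is the
exact adjoint of the reconstruction, which gives every reconstruction test
an analyzable ground truth.  For each angle, each scatterer is transformed
into the slice frame `(l, e, a)`.  It contributes only if `|e|` is inside
the elevational acceptance

`e_max(a) = max(|a − F| / (2 f#), w₀/2)`,

the constant-f-number aperture of the defocused beam, floored at the
diffraction-scale beam waist `w₀ = λ·f#` (≈ 0.84 mm for the reference
probe) so the focal plane keeps a finite thickness — with a strictly conic
acceptance, a scatterer at the focal depth but off the axis would be
invisible at almost every discrete angle, which no physical beam does.
The detected amplitude is tapered by an elevational sensitivity window on
`u = |e|/e_max` (default Gaussian with σ = e_max/2; hann and rect are
available for ablation), and a 2-cycle Gaussian-windowed tone burst at the
carrier (fractional −6 dB bandwidth 0.6, a typical figure for a 10 MHz
array) is deposited at the apparent axial position
`F ± sqrt(e² + (a−F)²)`, linearly split across the two nearest lateral
columns to avoid grid locking.  RF is the real part of the analytic
signal, IQ the analytic signal itself, envelope its magnitude.

Not modelled: attenuation, refraction, multiple scattering, lateral
diffraction (the in-plane PSF is one to two columns wide by construction),
element directivity, transmit sequencing.  Passing tests therefore
demonstrate the geometric correctness and self-consistency of the SAF
summation, not robustness to aberration or noise of real tissue data.

Cyst phantoms follow the reference recipe: scatterers uniform in a
20×20×20 mm block (default 10,000), amplitudes drawn from a normal
distribution centred at 0.5 with σ = 0.25 truncated to [0, 1] (the source
recipe states only "between 0 and 1, normally distributed"; a mean-centred
truncated normal covers the stated support), zeroed inside the cyst
sphere.

## Reconstruction

`reconstruct_saf` uses a gather formulation: per voxel and angle it reads
the slice at the voxel's own `(l, apparent depth)` and accumulates with the
weight `w_apo(u) · max(|l|, l₀)`.  This is mathematically the same
summation as expanding each slice into an arc volume, rotating and adding
(the scatter formulation), but avoids resampling rotated volumes; the
brute-force oracle preserves the equivalence check.  Choices:

* **Aperture growth** `e_max = |a − F| / (2 f#)`, with independent
  f-numbers below/above the focus (both default 5.625).  The reconstruction
  side uses the strict conic law (no waist floor): `e_max(0) = 0`.
* **Apodization** over the admitted extent; hann is the package default.
* **Slice-density weight** `|l|` floored at one lateral pixel (0.2 mm):
  the multiplier would otherwise null the axis voxels, which every slice
  samples anyway.
* **Signal mode.**  `incoherent_envelope` (default): envelope slices are
  accumulated; before gathering, the envelope is band-limited along depth
  with a moving average one output voxel wide (configurable via
  `envelope_smoothing_mm`), the usual anti-aliasing step when a ~0.05 mm
  pulse envelope is sampled onto 0.2 mm voxels — without it the peak is
  lost to sub-voxel quantization.  `coherent_rf`/`coherent_iq` accumulate
  signed/complex samples and take the magnitude of the sum at the end.
* **Normalization** divides by the accumulated weight where positive
  (default), making a uniform unit-envelope stack reconstruct to 1 inside
  the insonified support; per-angle-count and raw sums are available.
* **Interpolation** is bilinear in (lateral, axial) by default, nearest
  available for speed; out-of-range reads are zero.
* **Depth zoning**: one focal parameter per reconstruction; stitching
  depth zones with different `F` is done by running per-zone configs over
  the corresponding z-ranges of the output grid.

`reconstruct_baseline` is the no-SAF comparator: per voxel, the one or two
slices nearest in azimuth are sampled at the voxel's true radius and depth
(triangular weight over one angular step, both lateral signs of each
plane), i.e. plain scan conversion with the same normalization machinery.

### Coherent vs incoherent compounding

The two modes serve different studies, and the experiment drivers pick
accordingly.  Point-target resolution runs use `coherent_iq` with a
hamming window: simulated point data are phase-consistent across the
sweep, and only coherent summation realizes the synthetic aperture's
resolution gain (the incoherent arc-overlap gain is bounded by the arc
thickness over the crossing angle).  Hamming was preferred after
inspecting the method's own point-spread profiles: rect leaves a sidelobe
pedestal that merges with the mainlobe near the focus, hann pays ~5 % more
mainlobe width.  Cyst contrast runs use the incoherent default: speckle
phase decorrelates between angles, and envelope compounding reduces
speckle variance, which is what drives CNR.  On real mechanically rotated
data, angle-to-angle phase stability would decide whether the coherent
mode is usable at all — a known limitation of this desk-scale validation.

## Metrics

Circumferential resolution: axial-MIP of the reconstruction, sampled
bilinearly along the circle about the rotation axis through the target;
FWHM of that profile with the profile **minimum as baseline** (profiles
over speckle or partially-insonified rings never reach zero) and
sub-sample linear interpolation of the half-maximum crossings.  Circular
profiles are treated as periodic (the peak is re-centred before the
crossing search); multi-peak profiles report the global peak only.

CNR follows the signed definition
`(μ_t − μ_b)/sqrt(σ_t² + σ_b²)`; for anechoic targets the experiment
drivers report its magnitude, since a dark lesion yields a negative signed
value while detectability is sign-agnostic.  Default windows: a disc of
half the cyst diameter (target) and an equal-area annulus starting at 1.5×
the cyst radius (background), evaluated on the B-scan (lateral × axial
through the cyst centre) and C-scan (lateral × elevational at the cyst
depth).  Improvement rates are `(before − after)/before` for FWHM and
`(after − before)/before` for CNR, in percent, computed from unrounded
values.

## Study conditions and problem sizes

The reference evaluation uses the full 180-slice, 1° sweep.  Point targets
sit at depths {20, 30, 100} mm × offsets {2, 4, 6} mm from the rotation
centre (the focus at 45 mm separates the shallow and deep zones);
reconstruction ROIs are 0.2 mm isotropic, spanning the target's rotation
circle plus 1.5 mm margin in-plane and ±2 mm in depth.  Cyst trials use a
6 mm cyst at 30 mm depth, 3 mm off-centre, with a 2,000-scatterer block —
a desk-scale stand-in for the 10,000-scatterer recipe that keeps a full
trial at a few seconds while leaving the speckle dense enough for stable
window statistics; three seeds are averaged.  The bundled `demo` halves the
angular sampling (2°) and shrinks the phantoms further.

## Known limitations

* The forward model shares its geometry with the reconstruction; agreement
  between them validates the implementation, not the virtual-source
  approximation itself against full wave physics.
* Near the focal depth the admitted aperture shrinks to nothing and SAF
  cannot (and does not claim to) improve resolution; the evaluation
  excludes ±10 mm around the focus.
* No rotation-error, tilt or wobble compensation: angles are assumed exact.
* The baseline comparator interpolates between the two nearest slices;
  other scan-conversion kernels would shift baseline numbers slightly.
* CNR windows are fixed-geometry; no observer model beyond CNR.
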