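# rotsaf — elevational synthetic aperture focusing for rotational 3D ultrasound

Rotating a 1D linear array about its axial axis is a compact way to acquire
3D ultrasound, but the elevational beam thickness of the array smears every
off-plane target along the rotation arc.  `rotsaf` implements an elevational
**synthetic aperture focusing (SAF)** reconstruction for this geometry that
operates on *in-plane beamformed* slice data (RF, IQ or envelope) — no
per-element channel access required — together with a matched virtual-source
forward simulator and the evaluation metrics used to quantify the gain
(circumferential FWHM on MIP images, cyst CNR).

It is intended for researchers building rotational 3D ultrasound systems who
want to post-process the slice stacks their scanner already produces.

## Method

The elevational focus of the array (depth `F`) acts as a virtual point
source: an echo detected in the imaging plane at depth `a` may originate
from any point on the elevational arc

```
S_back(l, a, e, θ) = S_detect(l, F ± sqrt(e² + (a − F)²), θ),
```

with the `+` branch below the focus and the mirrored `−` branch above it.
The reconstruction gathers, for every output voxel `v` and rotation angle
`θ`, the slice-frame coordinates `(l, e, a) = R_z(−θ)(v − c)` and accumulates

```
B_SAF(v) = Σ_θ  w_apo(e) · w_ag(e) · max(|l|, l₀) · S_back(l, a, e, θ),
```

where `w_ag` gates the elevational aperture to `|e| ≤ |a − F| / (2 f#)`
(constant-f-number aperture growth), `w_apo` is the apodization window, and
the `|l|` factor compensates the higher slice density near the rotation
axis (floored at one lateral pixel `l₀` so the axis stays defined).  Sums
may be coherent (complex analytic signal) or incoherent (envelope
compounding); the accumulated weight per voxel is kept alongside the values
for normalization.  A plain scan-conversion baseline (`reconstruct_baseline`)
and an unoptimized brute-force oracle (`reconstruct_saf_bruteforce`) share
the same contract.

Resolution is evaluated as the FWHM of the intensity profile sampled along
a circle about the rotation axis on the axial MIP (the direction in which
the rotation smears); contrast as
`CNR = (μ_t − μ_b) / sqrt(σ_t² + σ_b²)` between a disc inside a cyst and an
equal-area annulus in the adjacent speckle.

## Worked example

```
$ rotsaf demo -o demo --seed 0
wrote demo/report.json
```

`demo/report.json` (abridged; 90 slices at 2°, 0.2 mm voxels):

```json
{
  "point": {
    "depth": 25.0, "offset": 3.0,
    "fwhm_baseline": 2.289, "fwhm_saf": 1.181,
    "fwhm_reduction_percent": 48.4, "peak_offset_mm": 0.1
  },
  "cyst": {
    "diameter": 5.0, "depth": 30.0, "offset": 2.0,
    "cnr_bscan_baseline": 0.152, "cnr_bscan_saf": 0.221,
    "cnr_bscan_gain_percent": 46.0,
    "cnr_cscan_baseline": 0.365, "cnr_cscan_saf": 0.475,
    "cnr_cscan_gain_percent": 30.2
  }
}
```

A point target 3 mm off the rotation centre at 25 mm depth (20 mm from the
elevational focus) is smeared to 2.29 mm along its rotation circle without
SAF; the SAF reconstruction narrows it to 1.18 mm (−48 %) and localizes the
peak to within half a voxel.  The anechoic cyst becomes more detectable in
both the B-scan and C-scan windows.

The same pipeline is scriptable step by step:

```
rotsaf simulate   -c examples/point_target.yaml -o stack.h5
rotsaf reconstruct -i stack.h5 -o volumes/          # writes saf/baseline .h5 + .nii
rotsaf evaluate   --saf volumes/saf.h5 --baseline volumes/baseline.h5 \
                  -o report.json --png-dir figs/
```

or driven from Python via `rotsaf.experiments.point_resolution_case` /
`cyst_contrast_trial`.

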