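# Anechoic 6 mm cyst, 30 mm deep, 3 mm off the rotation centre,
# in a 20 mm speckle block (2,000 scatterers, desk scale).
seed: 7
mode: rf
rotation: {start: 0, stop: 179, step: 1}
phantom:
  kind: cyst
  center: [3.0, 0.0, 30.0]
  diameter: 6.0
  n_scatterers: 2000
output_grid:
  origin: [-2.4, -5.4, 24.6]
  shape: [54, 54, 54]
  spacing: 0.2
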