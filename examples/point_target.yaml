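# Point target 4 mm from the rotation centre at 20 mm depth,
# full 180-slice sweep at 1 degree, reconstructed at 0.2 mm voxels.
seed: 1
mode: iq
rotation: {start: 0, stop: 179, step: 1}
phantom:
  kind: point
  position: [4.0, 0.0, 20.0]
saf:
  signal_mode: coherent_iq
  apodization_window: hamming
output_grid:
  origin: [-6.0, -6.0, 15.0]
  shape: [60, 60, 50]
  spacing: 0.2
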