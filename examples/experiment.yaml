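# Example experiment configuration for the optolight CLI.
#
#   optolight quantify    -c examples/experiment.yaml -o out/
#   optolight specificity -c examples/experiment.yaml -o out/
#   optolight simulate    -c examples/experiment.yaml -o out/   # writes OME-TIFFs
#
# Two acquisition fields under condition 7 (τ = 10 min), each a 512×512 px
# frame pairing an irradiated 512×256 region with an unirradiated control.
seed: 42
conditions: ["0", "7"]
generator:
  f_leak: 0.05
  cell_density_per_mm2: 8000.0
experiment:
  arms:
    - condition: "7"
      n_fields: 2
  n_frames: 12
  frame_interval_min: 120.0
params:
  prominence: 15.0
  bin_size: 50.0
channels: [nuclei, iRFP, EGFP, mCherry, stain]
save_stacks: false
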