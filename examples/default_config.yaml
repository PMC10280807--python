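# Annotated default pipeline configuration.
# Run with:  python examples/run_pipeline.py examples/default_config.yaml
stages: [simulate, detect, synchrony]   # executed in dependency order
out_dir: scratch/demo_run               # outputs + manifest.json
seed: 1                                 # single seed; stages get sub-seeds
params:
  population:
    n_cells: 4          # simultaneously imaged cells
    duration: 60.0      # s
    fs: 1000.0          # Hz
    spike_rate: 2.0     # Hz per cell
    uniform_weight: 0.4 # shared-input weight for every pair
    noise_sd: 0.004     # ΔF/F fraction per frame
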