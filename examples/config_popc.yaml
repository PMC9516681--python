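# Pipeline configuration (all keys optional; these are the defaults the
# CLI uses, shown for the membrane-like preset).
seed: 2024                  # root seed; per-stage seeds derive from it
temperature: 300.0          # K
preset: popc_like           # flat | square_barrier | popc_like | chol50_like
preset_params: {}           # preset-specific overrides (e.g. barrier, well)
segments:                   # umbrella windows: [z_start, z_end, spacing, k]
  - [0.0, 6.0, 1.0, 1.5]    # fine section near the bilayer center
  - [6.0, 37.5, 1.5, 0.5]   # coarse section out to bulk water
convention: half            # harmonic convention of k: half = ½k(z-z0)²
dt: 0.05                    # ps, Brownian-dynamics time step
n_steps: 40000              # production steps per window
n_equil_steps: 4000         # discarded equilibration steps
exchange_interval_steps: 200  # exchange attempts every 10 ps at dt=0.05
sample_every: 10            # subsampling stride for stored series
bin_width: 0.5              # Å, WHAM histogram bins
z_bulk: 37.5                # Å, coordinate treated as bulk water
combination: min            # headline rule: min | flip | out
diffusion_k: 2.5            # kcal/mol/Å², restraint for the D(z) stage
diffusion_n_steps: 40000
diffusion_repeats: 2        # independent restrained runs per window
metrics_n_frames: 400       # conformer frames for the metrics stage
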