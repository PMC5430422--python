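# Simulation configuration mirroring the handgrip instrument architecture.
# Usage: gripmr simulate --config examples/sim_config.yaml --out report.json
k: 2
eafs: [0.18, 0.18]
gammas: [-0.26, 0.47]
theta: 0.1
exposure_noise_sd: 3.4
outcome_kind: continuous
outcome_noise_sd: 1.0
n_exposure: 20000
n_outcome: 20000
n_reps: 200
seed: 42
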