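# Reduced-scale end-to-end study configuration.
# All randomness in the run derives from this one seed.
seed: 0
n_tonal_groups: 8          # sibling pairs per location (null = all 64)
max_reflection_order: 2
noise_rms: 0.1             # relative RMS; 0.1 -> 20 dB SNR
test_fraction: 0.10
n_trees: 300
gpr_restarts: 1
run_leave_out: true
run_parsimonious: true
srp_max_snippets: 2        # SRP baseline on this many test snippets
srp_cube_edge: 0.15
out_dir: results/study
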