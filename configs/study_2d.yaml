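# Full-scale study profile: multi-case mixed network with TSC inputs.
# All omitted keys take the package defaults, which equal the studied
# values (rho = 1000, nu = 1.85e-6, R0 = 0.05, x_center = 0.5,
# u_max = 0.00925, unit normalization 1 kg / 0.1 m / 10.811 s,
# batch schedule 160/160/160/160/3200, A in [0.015, 0.035],
# sigma in [0.10, 0.18], 16 training + 45 validation cases).
#
# NOTE: at these sizes training is a GPU-scale undertaking; for a
# CPU-scale verification run drop main_widths to e.g. [64, 64, 64]
# and iterations to a few thousand.

arch: mixed
use_tsc: true
multi_case_inputs: true
input_bias: true
main_widths: [856, 856, 856, 856]      # 2,214,475 trainable parameters

iterations: 100000
counts: [160, 160, 160, 160, 3200]     # 3840 points per iteration
pool_factor: 1000
iterations_per_epoch: 1000             # 3.84 M spatial points per epoch
learning_rate: 1.0e-3
lr_min: 1.0e-5
log_every: 1000

gpinn: false                           # enable for the two-phase schedule
w_derivative: 1.0

seed: 0
output_dir: runs/study_2d
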