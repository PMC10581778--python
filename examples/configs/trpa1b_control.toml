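# Control-condition TRPA1b-like population: 12 cells, three 60 s heating
# cycles from a 6 degC hold to 40 degC, acquired at 2 kHz.
# Run:  thermoclamp simulate examples/configs/trpa1b_control.toml --out simulated
#       thermoclamp analyze  examples/configs/trpa1b_control.toml simulated

[protocol]
kind = "temp_cycles"
hold_temp = 6.0
peak_temp = 40.0
n_cycles = 3
cycle_duration = 60.0
sample_rate = 2000.0

[channel]
model = "piecewise"
i_ref = -25.0
t_ref = 6.0
q10_baseline = 1.59
threshold = 22.91
q10_activation = 11.09
second_breakpoint = 34.46
q10_supra = 3.26

[population]
n_cells = 12
between_cell_cv = 0.3
threshold_sd_C = 1.31
noise_sd = 2.0
seed = 1
condition = "control"
construct = "TRPA1b"

[schedule]
q10_factors = [1.0, 1.0, 1.0]
leak_factors = [1.0, 1.0, 1.0]
threshold_lost = [false, false, false]

[analysis]
downsample_to = 100.0
q10_floor = 3.0
min_seg_points = 5

[stats]
alpha = 0.05
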