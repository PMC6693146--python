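bin_width: 0.1
classes:
- BV
- FV
- HM
- WM
- R
intensity_threshold: 300000.0
lockmass: 554.26
mode: all_data
mz_end: 1100.0
mz_start: 400.0
n_individuals_per_class: 8
n_shuffles: 0
n_trees: 300
pellets_per_individual: 3
r_min: 0.9
seed: 11
target: class
top_k: 5
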