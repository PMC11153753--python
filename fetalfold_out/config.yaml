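cohort_csv: /tmp/pytest-of-root/pytest-7/cohort0/cohort.csv
fdr_q: 0.05
kernel_diameter: 15.0
merge_ridge: 0.02
mesh_dir: null
n_regions: 21
out_dir: fetalfold_out
seed: 0
smooth_iters: 10
spacing: 0.75
standardize: true
tau_area: 0.05
tau_depth: 0.2
tau_position: 0.2
template_mesh: /tmp/pytest-of-root/pytest-7/cohort0/meshes/s000.off
w_area: 0.3333333333333333
w_depth: 0.3333333333333333
w_position: 0.3333333333333333
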