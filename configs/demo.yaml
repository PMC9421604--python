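collapse_at: 4
cvr_deficit: 0.05
effect_spec:
  lacune_count: 0.26
  wmh_norm_log10: 0.65
erosion_mm: 2.5
gradient_slope: 0.015
grid_shape:
- 72
- 80
- 48
min_voxels: 5
n_clusters: 3
n_imaging: 10
n_patients: 60
n_shells: 3
noise_sd: 0.02
out_dir: demo_run
seed: 0
shell_thickness: 2.0
t_mode: paired
ventricle_dilation_mm: 2.5
vif_threshold: 5.0
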