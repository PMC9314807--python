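# Demo pipeline: simulate a small cylinder-in-agar phantom at the
# 10-rotation specimen-session geometry, then run the external-field
# chi_i/chi_a fit and the sin^2(theta) residual fit.
# Run from the repository root:  oriqsm run --config configs/demo_specimen.yaml
# Relative paths resolve against the current working directory.
seed: 0
stages:
  - stage: simulate
    out_dir: scratch/demo_sim
    orientation_source: specimen
    params:
      grid_shape: [48, 48, 48]
      radius_voxels: 3
      length_voxels: 24
      noise_sd_ppb: 0.0
  - stage: specimen_fit
    sim_dir: scratch/demo_sim
    specimen_id: demo_cylinder
    out_csv: results/demo_specimen_fit.csv
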