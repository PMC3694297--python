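# Full pipeline on simulated inputs at the study conditions.
# Replace any `simulate` block with `path: <your.csv>` to analyse real data.
output_dir: results/pipeline
seed: 20260923

geometry:
  area_cm2: 1.13
  donor_volume_ml: 0.5
  receiver_volume_ml: 1.5

benchmark:
  min_teer_ohm_cm2: 500.0
  max_sucrose_papp_cm_s: 8.0e-6

teer:
  simulate:
    n_inserts: 91
    mean_teer_ohm_cm2: 789.0
    sd_teer_ohm_cm2: 171.7
    blank_ohm: 120.0

permeability:
  simulate:
    true_papp_cm_s: 6.07e-6
    n_inserts: 29
    noise_model: poisson

uptake:
  simulate:
    vd_control_ul_mg: 20.0
    factor: 1.34
    nonspecific_vd_ul_mg: 5.0
    noise_sd: 0.05

alp:
  simulate:
    group_activities_au_mg: {PBEC: 25.0, RBE4: 1.25}

qpcr:
  simulate:
    gene_folds: {BCRP: 1.5, occludin: 1.2, claudin5: 1.1}
    replicate_sd: 0.15
  test_prefix: test
  calibrator_prefix: calib

screen:
  simulate: {}
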