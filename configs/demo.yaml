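# Demo pipeline configuration.
# Generate the matching cohort first:
#   hgclust simulate --out demo --seed 17
# then:
#   hgclust run --config configs/demo.yaml
survey: demo/survey.csv
cord: demo/cord.csv
biomarkers: demo/biomarkers.csv
output_dir: demo_out
seed: 17
k_min: 4
k_max: 8
bootstrap_B: 60
min_explained: 0.5
min_sq_corr: 0.6
blood_to_hair: 0.25
threshold_ugg: 5.0
min_measurements: 10
lmem_bootstrap: 100
mice_m: 5
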