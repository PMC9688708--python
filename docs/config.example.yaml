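# Example pipeline configuration (all keys mirror PipelineConfig).
# Run with:  spaclust run-all --config docs/config.example.yaml --out results/run

# simulate | timeseries_dir | feature_tables
input_mode: simulate

# synthetic cohort (simulate mode); separation scales the planted
# between-group contrast (1.0 = study-design defaults)
cohort:
  n_subjects: 30
  seed: 0
  separation: 1.0

# for timeseries_dir mode: directory of per-subject TSV + JSON sidecars
# input_path: data/cohort
# for feature_tables mode: one CSV per condition
# feature_table_paths:
#   blue: results/features_blue.csv
#   red: results/features_red.csv

# feature pools for the constrained combination search
pools:
  pfc_pool: [O2Hb-PFC, HHb-PFC, tHb-PFC, StO2-PFC]
  vc_pool: [O2Hb-VC, HHb-VC, tHb-VC, StO2-VC]
  systemic_pool: [HR, MAP, SpO2, RR, PETCO2, SC]

k_range: [2, 9]
silhouette_threshold: 0.6
variance_threshold: 0.8

# subset of: kmeans kmedoids hierarchical gmm som dbscan
methods: [kmeans, kmedoids, hierarchical, gmm, som, dbscan]

# fix a combination to skip the exhaustive search (optional)
# combination: [HHb-PFC, O2Hb-VC, PETCO2, SC, SpO2]

top_n: 5
seed: 0

# subjects to drop before analysis (optional)
# exclude_subjects: [s17, s24]
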