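"""Run the full DCE-MRI analysis chain on a synthetic phantom cohort.

Simulates two groups of subjects (control-like fast influx vs disease-like
slow influx), normalizes to percent signal change against the quiet reference
region, PCA-denoises and ward-clusters the group-average time courses,
selects informative clusters, fits the kinetic model per subject per cluster,
and prints the per-cluster group comparison of the influx time constant.
"""

from glymflow import PipelineConfig, run_pipeline

config = PipelineConfig(seed=7, grid_shape=(32, 32, 24), n_subjects_per_group=5)
result = run_pipeline(config, out_dir="scratch/phantom_run")

for group, cmap in result.cluster_maps.items():
    print(f"{group}: {cmap.n_clusters} clusters, selected ids {cmap.selected_ids()}")

cols = ["cluster", "tau_in_AD_mean", "tau_in_AD_sem", "tau_in_CTL_mean",
        "tau_in_CTL_sem", "tau_in_p"]
print("\nper-cluster influx comparison (minutes, mean +/- sem; pooled t-test):")
print(result.comparison[cols].round(3).to_string(index=False))
print("\nLow p-values on caudal clusters reflect the planted slowdown of "
      "tracer influx in the disease-like group; artifacts are in "
      "scratch/phantom_run/.")
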