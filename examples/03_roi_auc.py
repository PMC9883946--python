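"""Region-of-interest AUC group comparison on a phantom cohort.

For each subject, voxel time courses are PCA-denoised, averaged within each
labelled region, and integrated over the observed window (trapezoid); a
two-sample t-test per region then compares cumulative tracer exposure across
groups.
"""

import numpy as np

from glymflow import matrix_from_series, normalize_series, roi_auc_analysis
from glymflow.synthetic import PhantomSpec, make_phantom_cohort

spec = PhantomSpec(grid_shape=(28, 28, 20), seed=21)
cohort = make_phantom_cohort(spec)

matrices, groups_of = {}, {}
for series in cohort.series:
    norm = normalize_series(series, cohort.truth.reference_mask,
                            brain_mask=cohort.truth.brain_mask)
    matrices[series.subject_id] = matrix_from_series(norm, cohort.truth.brain_mask)
    groups_of[series.subject_id] = series.group_label

some = next(iter(matrices.values()))
idx = some.voxel_index_map
row_labels = cohort.region_labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]]

table, comparisons = roi_auc_analysis(
    matrices, groups_of, row_labels, cohort.region_labels.names, some.frame_times_min
)

print("per-ROI AUC (percent*min), CTL vs AD:")
for name, cmp in sorted(comparisons.items()):
    a, b = cmp.group_names
    print(f"  {name:20s} {a}={cmp.group_means[0]:8.1f}+/-{cmp.group_sems[0]:6.1f}  "
          f"{b}={cmp.group_means[1]:8.1f}+/-{cmp.group_sems[1]:6.1f}  p={cmp.p_value:.4f}")
print("\nAUC is a model-free summary: regions whose generating kinetics "
      "retain tracer differently across groups separate here.")
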