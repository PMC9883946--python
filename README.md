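# glymflow

Analysis of glymphatic tracer transport from dynamic contrast-enhanced MRI
(DCE-MRI), for researchers studying brain-fluid circulation in rodent models.
After an intracisternal injection of a gadolinium tracer, T1-weighted volumes
acquired every 5 minutes from 30 to 150 minutes post-injection track the
tracer's influx into and clearance from brain tissue. `glymflow` turns such a
4D series into kinetic parameters and group statistics, and ships a seeded 4D
phantom generator so the whole chain is testable without animal data. A
companion module quantifies two-channel immunofluorescence histology
(vascular density, astrocyte signal, vessel coverage).

## The model

Each voxel-cluster time course of percent signal change is described by a
two-exponential influx/efflux model

```
f(t) = c1 · (1 − exp(−t/τ_in)) + c2 · (exp(−t/τ_out) − 1)
```

with gain constants c1, c2 ≥ 0 (percent), influx time constant τ_in and
efflux time constant τ_out (minutes; t = 0 at the start of infusion). The
model satisfies f(0) = 0 and f → c1 − c2 as t → ∞; its interior peak, when it
exists, is at t* = ln((c1·τ_out)/(c2·τ_in)) / (1/τ_in − 1/τ_out). Slowed
influx (larger τ_in) is the signature of impaired glymphatic transport.

The surrounding pipeline follows the standard recipe:

1. **Normalization** — intensities become percent signal change
   100·(x − m)/m, where m is the mean of a quiet reference ROI over the six
   consecutive frames with the least change in its mean trace; optional 3D
   Gaussian smoothing (never across time) with mask-renormalized weights.
2. **Denoising** — per-group (and per-subject) PCA over the frame dimension;
   the leading components (three suffice for >99% of the variability in
   contrast-injected cohorts) reconstruct low-noise time courses.
3. **Clustering** — agglomerative ward clustering of voxel time courses, cut
   at 15 clusters; clusters with ≥100 voxels and a mean-trace excursion
   >10 percentage points are selected for modelling (flat, noise-level
   clusters are what non-injected controls produce).
4. **Statistics** — per subject per cluster nonlinear least-squares fits
   (deterministic multi-start, log-parameterized time constants), then
   two-sample t-tests on τ_in and τ_out across groups; per-ROI trapezoid AUC
   comparisons as a model-free complement.

## Worked example

```sh
$ python examples/01_kinetic_model.py
generating params: c1=30.0, c2=28.0, tau_in=3.9 min, tau_out=46.0 min
fitted params:     c1=30.000, c2=28.000, tau_in=3.900 min, tau_out=46.000 min
sse=1.515e-28, converged=True, starts tried=8
time to peak: 10.81 min (when tracer arrival gives way to clearance)
AUC over the observed window: 862.1 percent*min (cumulative tracer exposure)
```

The fit recovers the generating parameters of a noiseless cluster-scale
curve exactly (residual at machine precision); the peak time and AUC
summarize when enhancement turns over and how much tracer the tissue saw.

`examples/02_phantom_pipeline.py` runs the full chain on a simulated
two-group cohort (control-like fast influx, disease-like slow influx):

```
CTL: 15 clusters, selected ids [4, 5, 6, 7, 9, 10, 11]

per-cluster influx comparison (minutes, mean +/- sem; pooled t-test):
 cluster  tau_in_AD_mean  tau_in_AD_sem  tau_in_CTL_mean  tau_in_CTL_sem  tau_in_p
       6          10.446          0.220            2.044           1.137     0.000
       ...
```

The disease-like group's fitted influx constants are several-fold larger in
the caudal clusters — the planted transport slowdown — while efflux does not
separate. `examples/03_roi_auc.py` and `examples/04_histology.py` demonstrate
the ROI-AUC and histology quantifications the same way.

A thin CLI wraps the same library code:

```sh
glymflow simulate --seed 1 --out-dir sim/
glymflow all --seed 1 --out-dir run/
glymflow histo --image pair.tiff --quantity vessel-density
```

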