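# clusterpose

Bone pose estimation from skin-mounted marker clusters, with a simulation
study of soft-tissue-artifact (STA) robustness.

In optical motion capture, joint kinematics are computed from clusters of
skin markers whose motion relative to the underlying bone (the soft tissue
artifact) is the dominant error source. `clusterpose` implements three bone
pose estimators that map a noisy marker cluster to a rigid segment pose
(R(t), **t**(t)) per time step:

* **SVD-LS** — the Kabsch-type singular-value-decomposition least-squares
  fit of a rigid transform between the static-calibration cluster and the
  observed cluster, with reflection correction (det R = +1).
* **PCT** — the classic Point Cluster Technique: markers are point masses
  whose masses are re-optimized each time step so that ‖λ(m, t)‖ matches
  the calibration eigenvalue norm ‖λ₀‖ of the cluster inertia tensor
  I(t) = Σⱼ mⱼ(‖rⱼ‖²𝟙 − rⱼrⱼᵀ); the pose is read off the principal axes
  and the mass-weighted CM. Matching only the *norm* leaves a solution
  manifold, which is why PCT produces discontinuous trajectories for many
  marker configurations and fails outright on clusters with rotational
  symmetry (repeated principal moments).
* **PCT-PT** — an extension of PCT built on first-order perturbation theory
  for symmetric matrices. Per time step the noisy inertia tensor is driven
  iteratively toward the calibration spectrum λ₀ via
  δλⱼ = eⱼᵀ δI eⱼ and δeⱼ = Σ_{i≠j} (eᵢᵀ δI eⱼ)/(λⱼ−λᵢ) eᵢ,
  with a step-halving schedule (s halved until acceptance, aborting below
  2⁻¹³, success at ‖λ₀ − λ_C‖ < 10⁻⁷). A single constant mass per marker is
  then recovered from the stacked 6·N_T tensor equations by
  Levenberg–Marquardt; the mass-weighted CM is constrained to lie within
  d_max of the cluster centroid and, depending on the sign of its
  projection onto the first denoised eigenvector, possibly reflected about
  the centroid. The orientation is the mean-centred least-squares rotation
  and therefore coincides exactly with SVD-LS.

The package also contains the simulation study used to compare the three
methods: conical-frustum surrogates for the thigh and the shank, virtual
4-marker configurations drawn uniformly within placement quadrants (with
rejection rules for minimum spacing), anatomical landmarks (ME/LE/FH/GT,
MM/LM/HF/TT), a periodic planar gait driver, quadrant-wise STA displacement
profiles (synthetic, or loaded from CSV), and the five reconstruction-offset
metrics TRO, eRO, ALRO, AFOO and KAO evaluated over the gait cycle and its
stance/swing phases.

## Worked example

```python
from clusterpose import SimulationConfig, GaitParameters, run_simulation

cfg = SimulationConfig(seed=1, n_configs=10, estimators=("pctpt", "svdls"),
                       gait=GaitParameters(sample_rate=60.0))
res = run_simulation(cfg)
s = res.summary
print(s[(s.phase == "GC") & s.metric.isin(["TRO", "eRO1", "KAO:FE"])]
      [["segment", "method", "metric", "mean", "std", "config_std", "units"]]
      .to_string(index=False))
```

prints

```
segment method metric     mean      std   config_std units
   knee  pctpt KAO:FE 0.175395 5.171108 1.335642e-01   deg
   knee  svdls KAO:FE 0.175395 5.171108 1.335642e-01   deg
  shank  pctpt    TRO 0.517127 0.310959 2.739955e-01    cm
  shank  pctpt   eRO1 2.328167 1.244464 3.839268e-01   deg
  shank  svdls    TRO 0.239842 0.121957 7.766107e-16    cm
  shank  svdls   eRO1 2.328167 1.244464 3.839268e-01   deg
  thigh  pctpt    TRO 1.042234 0.330880 6.956435e-02    cm
  thigh  pctpt   eRO1 4.452038 2.767521 6.303222e-01   deg
  thigh  svdls    TRO 0.763227 0.190805 7.699859e-16    cm
  thigh  svdls   eRO1 4.452038 2.767521 6.303222e-01   deg
```

Reading the table: `mean`/`std` pool all (configuration × time) samples of
the full gait cycle (GC); `config_std` is the across-configuration envelope
of the cycle-mean metric. Two structural results are visible. First, the
SVD-LS TRO envelope is zero to machine precision (`config_std ≈ 8e-16 cm`):
because every configuration receives the same quadrant-wise STA, the
observed centroid — which is exactly the SVD-LS CM estimate — is displaced
identically for every configuration. Second, the eRO and knee-angle rows
for PCT-PT and SVD-LS are identical: both use the mean-centred
least-squares rotation, and knee angles depend only on the frame axes.
The thigh errors exceed the shank errors because thigh STA is larger.

The same sweep is available from a shell:

```bash
clusterpose run -c examples/run.yaml -o out/          # end-to-end
clusterpose simulate -c examples/run.yaml -o rundir/  # write TRC trials
clusterpose estimate -d rundir/                       # pose CSVs
clusterpose evaluate -d rundir/                       # metric CSVs
clusterpose report   -d rundir/                       # tables + figures
```

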