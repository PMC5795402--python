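# bcsdeform

Predicting breast shape after breast-conserving surgery (BCS) with
tree-ensemble displacement regression on 3D point clouds.

After BCS the healing breast contracts around the excised volume, and
surgeons lack fast tools to show patients the likely aesthetic outcome.
Physically detailed finite-element simulations exist but take hours to
days; `bcsdeform` takes the machine-learning route: given a pre-surgery
breast point cloud and the clinical covariates of the planned excision
(BI-RADS density, tumor quadrant, tumor size class, laterality), it
predicts the displacement of every point,

```
P_pred = P_pre + f(P_pre, features),
```

so the predicted post-surgery shape is the pre-surgery cloud plus the
regressed displacement field. The package is aimed at researchers studying
learned surrogates for surgical-outcome simulation.

It provides, end to end:

* **geometry** — quadrant planes through the nipple, quadrant assignment
  (UOQ/UIQ/LOQ/LIQ), the excision cylinder perpendicular to the chest wall
  (`pi r^2 h = f V_breast`, excised fraction f ∈ {5, 7.5, 10}%), and
  damaged-point labelling;
* **synthetic data** — a seeded generator of paired pre/post clouds over
  the full 288-case factorial (6 patients × 4 densities × 4 quadrants × 3
  tumor sizes), with displacement magnitude decaying with distance from the
  excision, decreasing with density A→D, growing with tumor size S→L and
  mirroring with laterality; plus the density-weighted Mooney-Rivlin
  material table;
* **features** — 23 per-point features (coordinates, signed and Euclidean
  distances to the cylinder, cylindrical coordinates, one-hot clinical
  covariates), with all distance features zeroed for damaged points;
* **models** — per-axis random forests with leave-one-patient-out (LOPO)
  hyperparameter tuning under *average* (mean pair-wise distance) or
  *Hausdorff* (maximum) objectives, per-case training-row sampling,
  iterative adaptive point weighting (weights = clamped ceiling of the
  residual distance, range 1–6), gradient boosting and a joint multi-output
  forest;
* **heuristic baseline** — per-quadrant mean displacement, scaled in the
  tumor quadrant by density {A:4, B:3, C:2, D:1} and size {L:3, M:2, S:1}
  multipliers;
* **metrics** — pair-wise (corresponding-point) and bidirectional global
  (nearest-neighbour) distances, each reported as mean / standard deviation
  / maximum over surface points, against the no-change baseline.

## Worked example

Run a small LOPO experiment — three synthetic patients, 48 cases each,
60 surface + 90 interior points per cloud — comparing the tuned per-axis
random forest, the per-quadrant heuristic and the no-change baseline:

```python
from bcsdeform.models import TrainConfig
from bcsdeform.pipeline import RunConfig, run_experiment

cfg = RunConfig(
    n_patients=3, n_surface=60, n_interior=90,
    train=TrainConfig(n_trees_grid=(50,), max_features_grid=(8,), leaf_grid=(5,),
                      max_inner_folds=1, tune_sampling_rate=20, sampling_rate=65),
    models=("baseline", "heuristic", "rf"), objectives=("average",), seed=1,
)
report = run_experiment(cfg)
models = report["objectives"]["average"]["models"]
for name in report["objectives"]["average"]["ranking"]:
    p2p = models[name]["p2p"]
    print(f"{name:10s} p2p mu={p2p['mu']:.3f} mm  sigma={p2p['sigma']:.3f}  max={p2p['max']:.3f}")
```

prints

```
rf         p2p mu=1.405 mm  sigma=2.185  max=21.582
heuristic  p2p mu=2.554 mm  sigma=3.426  max=30.781
baseline   p2p mu=3.461 mm  sigma=4.594  max=37.136
```

Reading: with no prediction at all, corresponding surface points end up
3.46 mm (mean) from their healed positions on this dataset. The quadrant
heuristic removes the shared settling component (2.55 mm); the tuned forest
also learns the distance-decaying contraction around the excision and
more than halves the baseline error (1.41 mm). The maxima are dominated by
the large-displacement cases (dense-A breasts with large tumors). The same
ranking holds under the Hausdorff objective and at the reference scale
(6 patients, 288 cases; see `bcsdeform.pipeline.reference_config`).

A CLI mirrors the library for shell use:

```
bcsdeform generate --patients 6 --out-dir data/
bcsdeform report --patients 3 --models baseline,heuristic,rf --out report.json
bcsdeform evaluate --pred pred.ply --target post.ply --pre pre.ply --out eval.json
```

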