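# Methods

## Problem

Breast-conserving surgery (BCS) removes a tumor plus a margin of healthy
tissue; over the following year the wound heals and the breast contracts,
changing its shape. `bcsdeform` learns to predict that post-healing shape
directly from geometry: given a pre-surgery breast point cloud and the
clinical descriptors of the planned excision, it predicts the displacement
of every point, so the predicted post-surgery cloud is simply

```
P_pred = P_pre + disp_hat(P_pre, features)
```

Regressing displacements rather than absolute coordinates keeps breasts of
different size and laterality in a common target space.

## Coordinate frame and geometry

All geometry lives in one right-handed frame in millimetres: `x` =
medial→lateral of a right breast (mirrored for left breasts), `y` =
posterior→anterior (the chest wall near `y = 0`), `z` = inferior→superior.

Three planes discretize tumor location into the four clinical quadrants
(UOQ/UIQ/LOQ/LIQ): the **pectoral plane** is spanned by three annotated
corner points of the pectoral muscle (normal = normalised cross product,
oriented towards the nipple); the **superior–inferior plane** is parallel
to the `xy`-plane through the nipple; the **lateral–medial plane** is
perpendicular to the pectoral plane through the nipple and contains the
superior–inferior normal. Points exactly on a boundary go to the superior
/ lateral side (a deterministic tie-break; the lateral sense flips with
laterality).

The excised volume is approximated by a cylinder perpendicular to the chest
wall: its axis runs from the orthogonal projection of the tumor center onto
the pectoral plane towards the tumor; its height is the skin-to-muscle
extent along that axis (the largest axial projection over surface points);
its radius is solved from `pi r^2 h = f V_breast` with excised fraction
`f` ∈ {5%, 7.5%, 10%} for small/medium/large tumors (BCS eligibility caps
`f` at 20%). Points inside the cylinder are labelled damaged.

Because the axis is perpendicular to the chest wall, the "nearest pectoral
point" is realised as the orthogonal projection of the tumor center (a
discrete muscle mesh is out of scope), and the height is in effect the full
skin-to-muscle extent of the breast at any tumor position.

## Synthetic paired data

No public paired pre/post BCS dataset exists, so the package generates its
own study conditions. Each patient's breast is a half-ellipsoid attached to
a flat chest wall (semi-axes `a : 0.75a : a`), with surface points sampled
on the skin, interior points uniform in the volume, the nipple at the apex
and the breast volume set per size class (Small/Medium/Large targets
520 000 / 900 000 / 1 280 000 mm³ with ±8% per-patient jitter, spanning the
roughly 0.5–1.3 L range of clinical breast volumes). The default roster of
six patients balances 2 small / 2 medium / 2 large breasts and 3 left /
3 right, and the dataset enumerates the full factorial of patients × 4
BI-RADS densities × 4 tumor quadrants × 3 tumor sizes = 288 cases, each
with a derived per-case seed. Tumor centers are drawn uniformly inside the
target quadrant with rejection until the excision cylinder fits the
breast's lateral extent; for left breasts the tumor is sampled in the
mirrored right frame so that laterality is an exact mirror image.

The displacement field emulates the qualitative structure of published
healing simulations with two superposed components:

* **local contraction** — every point moves towards its target on the
  cylinder axis (the nearest axis point, pulled towards the base by the
  axial settling bias, default 0.5) by
  `A · exp(-d/λ) · (1 + ε)` mm, never past the target, where `d` is the
  distance to the excised cylinder (zero inside, so damaged points collapse
  towards the axis at full amplitude), `λ = 25` mm the decay length,
  `A = A₀ · b · s` with base amplitude `A₀ = 2` mm, density factors
  `b ∈ {A:4, B:3, C:2, D:1}` and size factors `s ∈ {L:3, M:2, S:1}`, and
  `ε` zero-mean Gaussian relative noise (sd 5%, clipped at ±0.5);
* **settling shift** — a per-quadrant constant posterior–inferior
  displacement (~0.7–1.1 mm, mirrored in `x` for left breasts), identical
  across cases except in the quadrant containing the tumor, where it is
  scaled by the same `b · s` factors: the operated quadrant settles in
  proportion to the excised volume and inversely with tissue stiffness.

The settling component is what gives the field reproducible non-zero
per-quadrant means. A purely centripetal contraction has vanishing quadrant
means, which would make any per-quadrant-mean predictor strictly worse than
doing nothing — contradicting the observed behaviour of physically
simulated healing that this generator emulates. With `A₀ = 0` and no noise
the generator emits exactly a per-quadrant-constant field with the
multiplier structure of the heuristic model, which is the self-consistency
fixture used in the tests.

Noise is keyed to (canonical-frame) point coordinates through a hash rather
than drawn sequentially, so the simulated field is a pure function of
geometry and seed — invariant under re-ordering of the cloud and exactly
mirrored between lateralities.

What the generator does **not** emulate: real skin/gland mechanics, gravity
and pose (prone/supine/upright) transformations, scar formation, wound
biochemistry, or anatomically detailed chest walls. Passing tests therefore
demonstrate that the learning machinery recovers displacement structure of
this class (smooth distance-decaying contraction plus quadrant-level
settling under factorial clinical covariates), not clinical accuracy on
real patients.

Material properties per density category are the tissue-mix weighted
Mooney-Rivlin constants `c1 = w·120 + (1-w)·80` Pa, `c2 = 0`,
`ρ0 = w·1020 + (1-w)·910` kg·m⁻³, with fibroglandular fractions
`w ∈ {A: 0.10, B: 0.35, C: 0.60, D: 0.85}`. They are carried as metadata;
the regression uses the density category itself.

## Features

Each pre-surgery point becomes one row with 23 features: centred
coordinates (px, py, pz); signed per-axis difference to the nearest point
of the cylinder axis segment (dispx, dispy, dispz); Euclidean distance to
the cylinder solid `d_cyl` (zero inside, making the damaged-point zero rule
a special case rather than an override); cylindrical coordinates
(ρ, φ, z_c) in the cylinder frame anchored at the base point, with φ
measured from the breast's lateral direction projected into the axis-normal
plane (any fixed convention works — the models only need consistency); and
one-hot encodings of tumor size (3), laterality (2), density (4) and tumor
quadrant (4). All distance-family features of damaged points are zero.
Targets are the per-axis displacements `post − pre`. Surface and interior
points both enter training; evaluation uses surface points only (the
clinically visible skin).

The axis segment (rather than the tumor center or the cylinder surface) is
the reference for the signed differences and the polar coordinates; this is
a documented convention choice applied consistently.

## Models

**Per-axis random forests (MISO)** — one `RandomForestRegressor` per axis.
**Gradient boosting** — per-axis `GradientBoostingRegressor` with weak
learners deliberately constrained to ≤3 leaves and depth ≤5
(friedman-mse splits). **Multi-output forest (MIMO)** — a single
`RandomForestRegressor` over the joint `(dx, dy, dz)` target, whose splits
score the three-axis variance reduction jointly.

Hyperparameters are tuned by grid search under an inner leave-one-patient-
out (LOPO) loop; candidates are scored by the pooled objective over inner
validation patients — mean pair-wise surface distance for the *average*
objective, maximum for *Hausdorff* — and ties break towards the cheapest
model (fewest trees, then fewest features, then smallest leaves). The full
reference grids (trees {5,…,500}, max-features {2,…,23}, leaf {1,…,5},
learning-rate {0.01,…,1}) are available via `TrainConfig.printed_grids()`;
the default configuration uses a coarsened grid, an optional randomized
grid subset, a reduced tuning subsample and a cap on inner folds — grid
content is an experiment knob, not method content. Training rows are
subsampled per case at a rate from {5%, 10%, …, 100%} (default 65%),
`ceil(rate · n)` rows without replacement; test rows are never subsampled.

**Adaptive weighting** — training points are re-weighted by the clamped
ceiling of their residual pair-wise distance (range 1–6: a point 0.3 mm off
gets weight 1, a point 4.2 mm off gets 5, anything ≥6 mm gets 6). The loop
refits, recomputes residuals and weights, and stops after 100 iterations or
when the objective has not improved for 3 consecutive iterations; the
best-objective model seen — which includes the initial unit-weight model —
is returned. Residuals are estimated **out-of-bag** by default (each point
predicted only by trees that did not train on it): pilot comparisons showed
that plain in-sample residuals of a forest are biased toward zero and
reward weights that chase fitting noise, degrading held-out error, whereas
OOB selection tracks genuine point difficulty and never returns a model
worse than unweighted under its own objective. `adaptive_residuals =
"insample"` restores the plain variant.

## Evaluation

Predicted and true post-surgery surface clouds are compared with:

* **pair-wise distance** — Euclidean distance between index-corresponding
  points: mean μ, standard deviation σ (population convention, divisor N)
  and maximum;
* **global distance** — directed mean nearest-neighbour distance, reported
  separately in both directions (nearest-neighbour ties resolve to the
  lowest index, making reports deterministic).

The **baseline evaluation** uses the pre-surgery cloud as the prediction —
the error a clinician would make by assuming no shape change — and is the
reference any model must beat. Outer evaluation is LOPO: all cases of one
patient form the test fold; per-point distances are pooled across test
cases and folds before the statistics are taken, and the reported maximum
is the global maximum over the pooled points.

## Reference experiment and problem sizes

`reference_config()` defines the package's reference desk experiment: 6
patients, the full 288-case factorial, 100 surface + 150 interior points
per cloud, 65% sampling, a two-candidate grid (50 trees, max-features
{8, 16}, leaf 5) scored on a 10% subsample with one inner fold, both
objectives. These problem sizes keep the complete two-objective comparison
within minutes on a single CPU while exercising every structural element of
the protocol; on this configuration the tuned per-axis forest reaches a
pooled pair-wise mean around 1.0 mm versus ≈2.4 mm for the per-quadrant
heuristic and ≈3.4 mm for the baseline, reproducing the expected ranking
direction under both objectives. The companion studies use 10 derived
seeds each on 2-patient datasets (50 surface + 75 interior points): the
paired adaptive-weighting comparison and the grouped feature-importance
ranking (where the distance-to-cylinder group is consistently among the
top groups, as the generator's decay law predicts).

## Heuristic baseline

The heuristic model estimates, per quadrant and axis, the mean displacement
pooled over the *healthy* occurrences of that quadrant in the training
cases (cases whose tumor lies elsewhere). Prediction displaces every point
by its quadrant's mean; in the quadrant containing the tumor the mean is
scaled by `b · s`. Pooling healthy occurrences (rather than all points) is
what makes the multipliers meaningful: they rescale an unoperated-quadrant
mean to the operated case, and on per-quadrant-constant data with matching
multipliers the fit-predict cycle is an exact identity. The model is
deliberately discontinuous across quadrant boundaries.

## Numerical choices and degenerate inputs

Collinear pectoral corners, non-positive cylinder heights and empty
quadrants raise informative errors; a cylinder radius exceeding half the
smallest breast extent logs a warning. The cylinder volume identity holds
to 1e-6 relative; plane containment and orthogonality to 1e-9. All
randomness flows from explicit seeds (per-case seeds derive from a CRC of
the case identity), so every artifact is reproducible from its config; the
experiment report is byte-identical across reruns and records a config
hash.

## Known limitations

* The generator's amplitudes are calibration, not ground truth — absolute
  millimetre errors are meaningful only relative to the baseline on the
  same data.
* The half-ellipsoid breast has no ptosis, no skin thickness and a planar
  chest wall.
* The multi-output forest uses the joint-variance split criterion of a
  standard multi-output random forest; other multivariate split criteria
  exist and may behave differently.
* Cylinder height derives from the global skin extent along the axis, so
  near the breast margin the cylinder can protrude laterally (it is only
  warned about, matching the tolerant behaviour of excision planning on
  coarse geometry).
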