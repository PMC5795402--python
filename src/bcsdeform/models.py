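"""Tree-ensemble displacement regression with leave-one-patient-out tuning.

The displacement of every pre-surgery point to its healed post-surgery
position is regressed per axis (one random forest each for x, y and z —
MISO), or jointly (one multi-output forest — MIMO), or with gradient
boosting.  Hyperparameters are tuned by grid search with an inner
leave-one-patient-out (LOPO) loop under one of two objective functions:

* ``average`` — the mean pair-wise distance between predicted and true
  post-surgery surface points;
* ``hausdorff`` — the maximum pair-wise distance.

Training rows can be subsampled per case at a configurable sampling rate,
and an optional adaptive-weighting loop re-weights training points by the
clamped ceiling of their residual distance (range 1–6), iterating until the
objective stops improving.
"""

from __future__ import annotations

import itertools
import warnings
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

from .features import FEATURE_COLUMNS, FEATURE_GROUPS, TARGET_COLUMNS, assemble_training_matrix, case_table, compute_features
from .geometry import BreastPCL, ExcisionCylinder
from .metrics import pairwise_distances
from .synthetic import CaseData, CaseSpec, stable_hash

logger = logging.getLogger(__name__)

#: Admissible per-case training sampling rates, %.
SAMPLING_RATES: tuple[int, ...] = tuple(range(5, 101, 5))

#: Weight clamp range for adaptive weighting.
WEIGHT_MIN, WEIGHT_MAX = 1, 6

AXES: tuple[str, ...] = ("x", "y", "z")


class SplitError(ValueError):
    """Not enough patients to form leave-one-patient-out folds."""


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration.

    The default grids are a coarsened subset of the full reference grids
    (``printed_grids``) sized for desk runs on a single CPU; grid content is
    an experiment knob, not method content.  ``tune_sampling_rate`` lets the
    grid search score candidates on a lighter subsample than the final fit;
    ``max_inner_folds`` caps the number of inner LOPO folds.
    """

    n_trees_grid: tuple[int, ...] = (50, 100, 200)
    max_features_grid: tuple[int, ...] = (4, 8, 16, 23)
    leaf_grid: tuple[int, ...] = (1, 3, 5)
    learning_rate_grid: tuple[float, ...] = (0.1,)
    objective: str = "average"  # "average" | "hausdorff"
    sampling_rate: int = 65
    tune_sampling_rate: int | None = None
    max_inner_folds: int | None = None
    max_grid_candidates: int | None = None
    seed: int = 0
    adaptive: bool = False
    max_adaptive_iters: int = 100
    patience: int = 3
    adaptive_residuals: str = "oob"  # "oob" | "insample"
    model_family: str = "rf"  # "rf" | "gbr" | "mor"

    def __post_init__(self) -> None:
        if self.objective not in ("average", "hausdorff"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.model_family not in ("rf", "gbr", "mor"):
            raise ValueError(f"unknown model family {self.model_family!r}")
        if self.adaptive_residuals not in ("oob", "insample"):
            raise ValueError(f"unknown adaptive_residuals {self.adaptive_residuals!r}")
        if self.sampling_rate not in SAMPLING_RATES:
            raise ValueError(f"sampling_rate must be one of {SAMPLING_RATES}")
        if not (self.n_trees_grid and self.max_features_grid and self.leaf_grid):
            raise ValueError("hyperparameter grids must be non-empty")

    @staticmethod
    def printed_grids() -> dict[str, tuple]:
        """The full reference hyperparameter grids."""
        return {
            "n_trees_grid": tuple(range(5, 501, 5)),
            "max_features_grid": tuple(range(2, 24)),
            "leaf_grid": tuple(range(1, 6)),
            "learning_rate_grid": tuple(round(0.01 * i, 2) for i in range(1, 101)),
        }

    def grid(self) -> list[dict]:
        """Hyperparameter candidates (cartesian product of the grids)."""
        lr_grid = self.learning_rate_grid if self.model_family == "gbr" else (None,)
        cands = [
            {"n_trees": t, "max_features": m, "leaf_size": l, "learning_rate": lr}
            for t, m, l, lr in itertools.product(
                self.n_trees_grid, self.max_features_grid, self.leaf_grid, lr_grid
            )
        ]
        if self.max_grid_candidates is not None and self.max_grid_candidates < len(cands):
            rng = np.random.default_rng(stable_hash("grid", self.seed))
            idx = rng.choice(len(cands), size=self.max_grid_candidates, replace=False)
            cands = [cands[i] for i in sorted(idx)]
        return cands


@dataclass
class DeformationModel:
    """A trained displacement regressor bundle (per-axis or multi-output)."""

    family: str
    regressors: dict[str, object]
    hyperparams: dict
    config: TrainConfig
    objective_value: float | None = None
    sample_weights: np.ndarray | None = None
    n_training_rows: int = 0

    def predict_displacement(self, features: pd.DataFrame) -> np.ndarray:
        """Predicted (n, 3) displacement for a feature table."""
        X = features[list(FEATURE_COLUMNS)].to_numpy()
        if self.family == "mor":
            return np.asarray(self.regressors["xyz"].predict(X))
        return np.column_stack([self.regressors[ax].predict(X) for ax in AXES])


def lopo_splits(
    cases: Sequence[CaseData],
) -> list[tuple[list[CaseData], list[CaseData]]]:
    """Leave-one-patient-out folds: one fold per patient, no overlap."""
    patients: list[str] = []
    for c in cases:
        if c.spec.patient_id not in patients:
            patients.append(c.spec.patient_id)
    if len(patients) < 2:
        raise SplitError("leave-one-patient-out needs at least 2 patients")
    folds = []
    for pid in patients:
        test = [c for c in cases if c.spec.patient_id == pid]
        train = [c for c in cases if c.spec.patient_id != pid]
        folds.append((train, test))
    return folds


def sample_points(table: pd.DataFrame, rate: int, seed: int = 0) -> pd.DataFrame:
    """Per-case uniform without-replacement subsample of training rows.

    Keeps ``ceil(rate% * n)`` rows of each case.  Rate 100 is the identity.
    """
    if rate not in SAMPLING_RATES:
        raise ValueError(f"sampling rate must be one of {SAMPLING_RATES}, got {rate}")
    if rate == 100:
        return table
    parts = []
    for case_id, group in table.groupby("case_id", sort=False):
        k = math.ceil(rate / 100.0 * len(group))
        rng = np.random.default_rng(stable_hash("sample", seed, rate, case_id))
        idx = rng.choice(len(group), size=k, replace=False)
        parts.append(group.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=False)


def weight_from_distance(p2p_distance) -> np.ndarray:
    """Adaptive weight: the ceiling of the residual distance, clamped to 1–6."""
    d = np.asarray(p2p_distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    w = np.clip(np.ceil(d), WEIGHT_MIN, WEIGHT_MAX)
    return w.astype(int) if w.ndim else int(w)


def _make_regressor(family: str, hp: dict, seed: int):
    if family in ("rf", "mor"):
        return RandomForestRegressor(
            n_estimators=hp["n_trees"],
            max_features=hp["max_features"],
            min_samples_leaf=hp["leaf_size"],
            random_state=seed,
            n_jobs=1,
        )
    if family == "gbr":
        # weak learners deliberately kept small: <= 3 leaves, depth <= 5
        return GradientBoostingRegressor(
            n_estimators=hp["n_trees"],
            max_features=hp["max_features"],
            min_samples_leaf=hp["leaf_size"],
            learning_rate=hp["learning_rate"] or 0.1,
            max_leaf_nodes=3,
            max_depth=5,
            criterion="friedman_mse",
            random_state=seed,
        )
    raise ValueError(f"unknown model family {family!r}")


def _fit_regressors(
    family: str,
    table: pd.DataFrame,
    hp: dict,
    seed: int,
    sample_weight: np.ndarray | None = None,
    oob: bool = False,
) -> dict[str, object]:
    X = table[list(FEATURE_COLUMNS)].to_numpy()
    with warnings.catch_warnings():
        # a handful of rows may lack OOB estimates at small tree counts
        warnings.filterwarnings("ignore", message=".*OOB.*", category=UserWarning)
        if family == "mor":
            reg = _make_regressor(family, hp, stable_hash("fit", seed, "xyz"))
            if oob:
                reg.set_params(oob_score=True)
            reg.fit(X, table[list(TARGET_COLUMNS)].to_numpy(), sample_weight=sample_weight)
            return {"xyz": reg}
        regs = {}
        for ax, target in zip(AXES, TARGET_COLUMNS):
            reg = _make_regressor(family, hp, stable_hash("fit", seed, ax))
            if oob:
                reg.set_params(oob_score=True)
            reg.fit(X, table[target].to_numpy(), sample_weight=sample_weight)
            regs[ax] = reg
    return regs


def _objective(distances: np.ndarray, objective: str) -> float:
    return float(np.max(distances)) if objective == "hausdorff" else float(np.mean(distances))


def _surface_residuals(model: DeformationModel, cases: Sequence[CaseData]) -> np.ndarray:
    """Pooled per-point p2p distances on the surface points of the cases."""
    out = []
    for case in cases:
        table = case_table(case)
        surf = table[table["is_surface"]]
        disp = model.predict_displacement(surf)
        pred = case.pre.points[: case.pre.n_surface] + disp
        out.append(pairwise_distances(pred, case.post.points[: case.post.n_surface]))
    return np.concatenate(out)


def tune_and_train(train_cases: Sequence[CaseData], config: TrainConfig) -> DeformationModel:
    """Grid-search hyperparameters with an inner LOPO loop, then refit.

    Candidates are scored by the pooled objective over the inner validation
    patients (mean pair-wise distance for the ``average`` objective, maximum
    for ``hausdorff``); ties break towards the cheapest model (fewest trees,
    then fewest features, then smallest leaves).  The winning configuration
    is refit on all training rows at the configured sampling rate (with
    adaptive weighting when enabled).
    """
    candidates = config.grid()
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    inner_folds = lopo_splits(list(train_cases))
    if config.max_inner_folds is not None:
        inner_folds = inner_folds[: config.max_inner_folds]
    tune_rate = config.tune_sampling_rate or config.sampling_rate

    scored = []
    for hp in candidates:
        dists = []
        for inner_train, inner_valid in inner_folds:
            table, _ = assemble_training_matrix(inner_train)
            sampled = sample_points(table, tune_rate, seed=config.seed)
            regs = _fit_regressors(config.model_family, sampled, hp, config.seed)
            probe = DeformationModel(config.model_family, regs, hp, config)
            dists.append(_surface_residuals(probe, inner_valid))
        value = _objective(np.concatenate(dists), config.objective)
        scored.append((value, hp))
        logger.debug("grid candidate %s -> %s = %.4f", hp, config.objective, value)

    best_value, best_hp = min(
        scored,
        key=lambda s: (
            s[0],
            s[1]["n_trees"],
            s[1]["max_features"],
            s[1]["leaf_size"],
            s[1]["learning_rate"] or 0.0,
        ),
    )
    logger.info("selected %s (inner %s = %.4f)", best_hp, config.objective, best_value)

    if config.adaptive:
        model = adaptive_weight_loop(train_cases, config, hyperparams=best_hp)
    else:
        table, _ = assemble_training_matrix(train_cases)
        sampled = sample_points(table, config.sampling_rate, seed=config.seed)
        regs = _fit_regressors(config.model_family, sampled, best_hp, config.seed)
        model = DeformationModel(
            config.model_family, regs, best_hp, config, n_training_rows=len(sampled)
        )
    model.objective_value = best_value
    return model


def train_multi_output(train_cases: Sequence[CaseData], config: TrainConfig) -> DeformationModel:
    """Tune and train a single multi-output (MIMO) forest over (dx, dy, dz).

    Splits are scored on the joint three-axis target (the native multi-output
    criterion of a random forest), contrasting with the per-axis MISO route.
    """
    return tune_and_train(train_cases, replace(config, model_family="mor"))


def adaptive_weight_loop(
    train_cases: Sequence[CaseData],
    config: TrainConfig,
    hyperparams: dict | None = None,
) -> DeformationModel:
    """Iterative adaptive re-weighting of training points.

    Starting from unit weights, the model is refit, its residual p2p
    distance per training point is mapped to a weight (ceiling clamped to
    1–6), and the loop repeats until the objective fails to improve for
    ``patience`` consecutive iterations or ``max_adaptive_iters`` is
    reached.  The best-objective model seen (which includes the initial
    unit-weight model) is returned.

    Residuals are estimated out-of-bag by default — each point predicted
    only by trees that did not see it — so the weights track genuine
    difficulty rather than in-sample fitting noise; set
    ``adaptive_residuals="insample"`` to use plain training residuals.
    """
    if config.model_family not in ("rf", "mor"):
        raise ValueError("adaptive weighting is defined for the random-forest family")
    use_oob = config.adaptive_residuals == "oob"
    if hyperparams is None:
        hyperparams = {
            "n_trees": config.n_trees_grid[0],
            "max_features": config.max_features_grid[0],
            "leaf_size": config.leaf_grid[0],
            "learning_rate": None,
        }
    table, _ = assemble_training_matrix(train_cases)
    sampled = sample_points(table, config.sampling_rate, seed=config.seed)
    targets = sampled[list(TARGET_COLUMNS)].to_numpy()
    surface_mask = sampled["is_surface"].to_numpy()

    weights = np.ones(len(sampled))
    best: DeformationModel | None = None
    best_value = np.inf
    stall = 0
    for iteration in range(config.max_adaptive_iters):
        regs = _fit_regressors(
            config.model_family,
            sampled,
            hyperparams,
            config.seed,
            sample_weight=weights,
            oob=use_oob,
        )
        model = DeformationModel(
            config.model_family,
            regs,
            hyperparams,
            config,
            sample_weights=weights.copy(),
            n_training_rows=len(sampled),
        )
        if use_oob:
            if config.model_family == "mor":
                pred = np.asarray(regs["xyz"].oob_prediction_)
            else:
                pred = np.column_stack([regs[ax].oob_prediction_ for ax in AXES])
        else:
            pred = model.predict_displacement(sampled)
        residuals = np.linalg.norm(pred - targets, axis=1)
        value = _objective(residuals[surface_mask], config.objective)
        if value < best_value - 1e-12:
            best, best_value, stall = model, value, 0
        else:
            stall += 1
            if stall >= config.patience:
                break
        weights = weight_from_distance(residuals).astype(float)
    assert best is not None
    best.objective_value = best_value
    logger.info(
        "adaptive loop stopped after %d iteration(s); best in-sample %s = %.4f",
        iteration + 1,
        config.objective,
        best_value,
    )
    return best


def predict(
    model: DeformationModel,
    pcl: BreastPCL,
    cyl: ExcisionCylinder,
    spec: CaseSpec,
    damaged: np.ndarray | None = None,
) -> tuple[BreastPCL, np.ndarray]:
    """Predict the post-surgery cloud: pre-surgery points plus displacement."""
    feats = compute_features(pcl, cyl, spec, damaged)
    disp = model.predict_displacement(feats)
    return pcl.with_points(pcl.points + disp), disp


def feature_importances(model: DeformationModel) -> dict[str, pd.DataFrame]:
    """Per-axis individual and grouped feature importances, in percent.

    Individual importances are the impurity-based importances of each
    regressor rescaled to sum to 100% per axis; grouped importances average
    the individual percentages within each feature group.
    """
    columns = {}
    for name, reg in model.regressors.items():
        if not hasattr(reg, "feature_importances_"):
            raise TypeError("model does not expose feature importances")
        imp = np.asarray(reg.feature_importances_, dtype=float)
        total = imp.sum()
        columns[name] = 100.0 * imp / total if total > 0 else imp
    individual = pd.DataFrame(columns, index=list(FEATURE_COLUMNS))
    grouped = pd.DataFrame(
        {
            group: individual.loc[list(members)].mean(axis=0)
            for group, members in FEATURE_GROUPS.items()
        }
    ).T
    return {"individual": individual, "grouped": grouped}
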