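"""Visual-score prediction with Random Forests and grouped cross-validation.

The unit of analysis is the slice, but slices of one patient are strongly
correlated, so evaluation uses leave-one-patient-out (LOPO) cross-
validation: each fold trains on all other patients' slices and predicts the
held-out patient's slices.  Hyperparameters (number of trees; fraction of
features considered per split) are selected by accuracy over the same CV,
which is the convention this package reproduces — note it is optimistically
biased, since the selection peeks at the evaluation folds.

Scores are treated as nominal classes; a training fold lacking a rare
score simply cannot predict it in that fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import feature_frame, range_grid

TREE_GRID = (10, 100, 1000)
FRACTION_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class RFConfig:
    """Random-Forest hyperparameters.

    ``feature_fraction`` is converted to an integer features-per-split as
    max(1, round(fraction x n_features)), rounding half up.
    """

    n_trees: int = 100
    feature_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must be in (0, 1]")

    def max_features(self, n_features: int) -> int:
        return max(1, math.floor(self.feature_fraction * n_features + 0.5))


@dataclass(frozen=True)
class FeatureCohort:
    """Per-slice feature vectors with scores and patient grouping."""

    X: np.ndarray
    y: np.ndarray
    patient_ids: tuple[str, ...]
    slice_ids: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2 or not (len(X) == len(y) == len(self.patient_ids)):
            raise ValueError("inconsistent cohort dimensions")
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")
        if len(set(self.patient_ids)) < 2:
            raise ValueError("cohort must contain at least 2 patients")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureCohort":
        """Build from a feature matrix with patient_id/slice_id/score."""
        meta = ("patient_id", "slice_id", "score")
        feats = [c for c in df.columns if c not in meta]
        return cls(
            X=df[feats].to_numpy(dtype=float),
            y=df["score"].to_numpy(dtype=int),
            patient_ids=tuple(df["patient_id"].astype(str)),
            slice_ids=tuple(df["slice_id"].astype(str)),
            feature_names=tuple(feats),
        )

    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SlicePrediction:
    slice_id: str
    patient_id: str
    true_score: int
    predicted_score: int


@dataclass(frozen=True)
class CVResult:
    """LOPO CV outcome: one prediction per slice plus the configuration."""

    records: tuple[SlicePrediction, ...]
    config: RFConfig
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        n_ok = sum(r.true_score == r.predicted_score for r in self.records)
        object.__setattr__(self, "accuracy", n_ok / len(self.records))

    def true_scores(self) -> list[int]:
        return [r.true_score for r in self.records]

    def predicted_scores(self) -> list[int]:
        return [r.predicted_score for r in self.records]


def _fit_forest(
    X: np.ndarray, y: np.ndarray, config: RFConfig
) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features(X.shape[1]),
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def select_features(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: RFConfig,
    keep_fraction: float,
) -> np.ndarray:
    """Indices of the top features by impurity importance on a training fold.

    A forest is fit on the fold, features are ranked by mean impurity
    decrease, and the top ceil(keep_fraction x n_features) are kept.  Ties
    resolve to the lower feature index so selection is deterministic.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    d = X_train.shape[1]
    n_keep = math.ceil(keep_fraction * d)
    if n_keep == d:
        return np.arange(d)
    importances = _fit_forest(X_train, y_train, config).feature_importances_
    order = np.argsort(-importances, kind="stable")
    return np.sort(order[:n_keep])


def lopo_folds(patient_ids: Sequence[str]) -> list[tuple[str, np.ndarray]]:
    """(held-out patient, boolean test-row mask) pairs, one per patient.

    The training fold for a patient is the complement of its mask, so no
    slice of the held-out patient ever reaches its own training set.
    """
    patients = np.asarray(patient_ids)
    return [(p, patients == p) for p in pd.unique(patients)]


def lopo_cv(
    cohort: FeatureCohort,
    config: RFConfig,
    keep_fraction: float | None = None,
) -> CVResult:
    """Leave-one-patient-out cross-validation of a Random Forest.

    When ``keep_fraction`` is given, importance-based feature selection is
    run inside each training fold (the held-out patient never influences
    which features are kept) and the forest is refit on the reduced schema.
    """
    records: list[SlicePrediction] = []
    for patient, test in lopo_folds(cohort.patient_ids):
        train = ~test
        X_tr, y_tr = cohort.X[train], cohort.y[train]
        X_te = cohort.X[test]
        if keep_fraction is not None:
            kept = select_features(X_tr, y_tr, config, keep_fraction)
            X_tr, X_te = X_tr[:, kept], X_te[:, kept]
        clf = _fit_forest(X_tr, y_tr, config)
        preds = clf.predict(X_te)
        for idx, pred in zip(np.flatnonzero(test), preds):
            records.append(
                SlicePrediction(
                    slice_id=cohort.slice_ids[idx],
                    patient_id=cohort.patient_ids[idx],
                    true_score=int(cohort.y[idx]),
                    predicted_score=int(pred),
                )
            )
    return CVResult(records=tuple(records), config=config)


def default_config_grid(seed: int = 0) -> list[RFConfig]:
    """The 15-point hyperparameter grid: trees x feature fraction."""
    return [
        RFConfig(n_trees=t, feature_fraction=f, seed=seed)
        for t in TREE_GRID
        for f in FRACTION_GRID
    ]


def grid_search(
    cohort: FeatureCohort,
    configs: Sequence[RFConfig],
    keep_fraction: float | None = None,
) -> tuple[CVResult, list[CVResult]]:
    """Evaluate every configuration by LOPO CV and return the best.

    The best configuration maximizes CV accuracy; ties break toward fewer
    trees, then toward a smaller feature fraction.
    """
    if not configs:
        raise ValueError("need at least one configuration")
    results = [lopo_cv(cohort, c, keep_fraction) for c in configs]
    best = min(
        results,
        key=lambda r: (-r.accuracy, r.config.n_trees, r.config.feature_fraction),
    )
    return best, results


def range_sweep(
    curves,
    scores: dict[str, int],
    configs_for_seed,
    kind: str,
) -> pd.DataFrame:
    """Best LOPO accuracy for every threshold sub-range.

    For each of the 21 (lower, upper) HU ranges, features are rebuilt for
    that range, the hyperparameter grid is searched, and the best accuracy
    recorded — the lower-triangular accuracy table, one row per range.

    ``configs_for_seed`` is either a sequence of RFConfig or a callable
    ``grid -> sequence`` (letting callers vary configs per range).
    """
    rows = []
    for grid in range_grid():
        df = feature_frame(curves, grid, kind, scores)
        cohort = FeatureCohort.from_frame(df)
        configs = (
            configs_for_seed(grid)
            if callable(configs_for_seed)
            else configs_for_seed
        )
        best, _ = grid_search(cohort, configs)
        rows.append(
            {
                "lower_hu": grid.lower_hu,
                "upper_hu": grid.upper_hu,
                "kind": kind,
                "accuracy": best.accuracy,
                "n_trees": best.config.n_trees,
                "feature_fraction": best.config.feature_fraction,
            }
        )
    return pd.DataFrame(rows)
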