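"""Random-Forest LOPO cross-validation, grid search, feature selection."""

import numpy as np
import pandas as pd
import pytest

from heq.prediction import (
    CVResult,
    FeatureCohort,
    RFConfig,
    default_config_grid,
    grid_search,
    lopo_cv,
    range_sweep,
    select_features,
)


def _cohort(X, y, patients):
    n, d = X.shape
    return FeatureCohort(
        X=X,
        y=y,
        patient_ids=tuple(patients),
        slice_ids=tuple(f"s{i}" for i in range(n)),
        feature_names=tuple(f"f{j}" for j in range(d)),
    )


@pytest.fixture
def separable_cohort():
    """The single feature literally equals the score; 12 patients x 3
    slices, so every forest predicts perfectly regardless of config."""
    y = np.repeat(np.tile(np.arange(6), 2), 3)
    X = y.astype(float).reshape(-1, 1)
    patients = np.repeat([f"P{i}" for i in range(12)], 3)
    return _cohort(X, y, patients)


class TestRFConfig:
    @pytest.mark.parametrize(
        "fraction,n,expected",
        [(0.1, 60, 6), (0.1, 15, 2), (0.1, 5, 1), (0.9, 120, 108),
         (0.01, 10, 1)],
    )
    def test_max_features_rounds_half_up_floored_at_one(
        self, fraction, n, expected
    ):
        assert RFConfig(feature_fraction=fraction).max_features(n) == expected

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            RFConfig(feature_fraction=0.0)

    def test_grid_has_fifteen_configs(self):
        grid = default_config_grid()
        assert len(grid) == 15
        assert {c.n_trees for c in grid} == {10, 100, 1000}
        assert {c.feature_fraction for c in grid} == {0.1, 0.3, 0.5, 0.7, 0.9}


class TestLopoCV:
    def test_separable_cohort_is_perfect(self, separable_cohort):
        result = lopo_cv(separable_cohort, RFConfig(n_trees=10, seed=0))
        assert result.accuracy == 1.0

    def test_one_prediction_per_slice(self, separable_cohort):
        result = lopo_cv(separable_cohort, RFConfig(n_trees=10))
        assert sorted(r.slice_id for r in result.records) == sorted(
            separable_cohort.slice_ids
        )

    def test_reproducible_given_seed(self, separable_cohort):
        a = lopo_cv(separable_cohort, RFConfig(n_trees=10, seed=3))
        b = lopo_cv(separable_cohort, RFConfig(n_trees=10, seed=3))
        assert a.records == b.records

    def test_single_class_training_fold_predicts_that_class(self):
        X = np.ones((6, 2))
        y = np.array([2, 2, 2, 2, 2, 2])
        cohort = _cohort(X, y, ["A", "A", "A", "B", "B", "B"])
        result = lopo_cv(cohort, RFConfig(n_trees=10))
        assert all(r.predicted_score == 2 for r in result.records)

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            _cohort(np.ones((3, 2)), np.zeros(3, int), ["A", "A", "A"])

    def test_no_leakage_between_patients(self, separable_cohort):
        """The held-out patient never appears in its own training fold, and
        removing a patient changes other folds only by that removal."""
        from heq.prediction import lopo_folds

        ids = np.asarray(separable_cohort.patient_ids)
        slices = np.asarray(separable_cohort.slice_ids)
        full = {
            p: set(slices[~test]) for p, test in lopo_folds(ids)
        }
        for p, train in full.items():
            assert not train & set(slices[ids == p])
        keep = ids != "P0"
        reduced = {
            p: set(slices[keep][~test])
            for p, test in lopo_folds(ids[keep])
        }
        removed = set(slices[ids == "P0"])
        for p, train in reduced.items():
            assert train == full[p] - removed


class TestGridSearch:
    def test_single_config_returned(self, separable_cohort):
        cfg = RFConfig(n_trees=10, feature_fraction=0.5)
        best, results = grid_search(separable_cohort, [cfg])
        assert best.config == cfg and len(results) == 1

    def test_tie_breaks_toward_fewer_trees_then_smaller_fraction(
        self, separable_cohort
    ):
        configs = [
            RFConfig(n_trees=100, feature_fraction=0.5),
            RFConfig(n_trees=10, feature_fraction=0.9),
            RFConfig(n_trees=10, feature_fraction=0.5),
        ]
        best, results = grid_search(separable_cohort, configs)
        assert all(r.accuracy == 1.0 for r in results)  # all tie
        assert best.config.n_trees == 10
        assert best.config.feature_fraction == 0.5

    def test_best_dominates_every_member(self, separable_cohort):
        configs = [
            RFConfig(n_trees=t, feature_fraction=f)
            for t in (10, 100)
            for f in (0.1, 0.5)
        ]
        best, results = grid_search(separable_cohort, configs)
        assert all(best.accuracy >= r.accuracy for r in results)

    def test_empty_grid_rejected(self, separable_cohort):
        with pytest.raises(ValueError):
            grid_search(separable_cohort, [])


class TestSelectFeatures:
    def test_keep_all_is_identity(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(30, 10)), rng.integers(0, 3, 30)
        kept = select_features(X, y, RFConfig(n_trees=10), 1.0)
        assert (kept == np.arange(10)).all()

    def test_keep_half_of_ten(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(30, 10)), rng.integers(0, 3, 30)
        kept = select_features(X, y, RFConfig(n_trees=10), 0.5)
        assert len(kept) == 5

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_features(np.ones((4, 2)), np.zeros(4, int),
                            RFConfig(), 1.5)

    def test_informative_features_retained_more_than_noise(self):
        """5 informative + 55 noise features: across seeds, importance-based
        selection keeps informative columns at a higher rate."""
        inf_rate, noise_rate = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.tile(np.arange(6), 8)
            signal = np.column_stack(
                [y + rng.normal(0, 0.3, len(y)) for _ in range(5)]
            )
            noise = rng.normal(size=(len(y), 55))
            X = np.column_stack([signal, noise])
            kept = select_features(
                X, y, RFConfig(n_trees=50, seed=seed), 0.5
            )
            inf_rate.append(np.isin(np.arange(5), kept).mean())
            noise_rate.append(np.isin(np.arange(5, 60), kept).mean())
        assert np.mean(inf_rate) > np.mean(noise_rate)

    def test_selection_inside_fold_changes_only_schema(self, separable_cohort):
        result = lopo_cv(
            separable_cohort, RFConfig(n_trees=10, seed=0), keep_fraction=0.5
        )
        assert len(result.records) == len(separable_cohort.slice_ids)
        assert result.accuracy == 1.0  # informative feature survives


class TestRangeSweep:
    def test_sweep_produces_21_cells_and_matches_full_range(
        self, small_cohort, small_cohort_curves
    ):
        scores = {s.ct.slice_id: s.score for s in small_cohort.slices}
        configs = [RFConfig(n_trees=10, feature_fraction=0.3, seed=0)]
        table = range_sweep(small_cohort_curves, scores, configs, "heq")
        assert len(table) == 21
        assert set(zip(table.lower_hu, table.upper_hu)) == {
            (lo, hi)
            for lo in range(-1000, -700, 50)
            for hi in range(lo + 50, -650, 50)
        }
        from heq.core import FULL_GRID
        from heq.features import feature_frame

        df = feature_frame(small_cohort_curves, FULL_GRID, "heq", scores)
        direct = lopo_cv(FeatureCohort.from_frame(df), configs[0])
        cell = table[(table.lower_hu == -1000) & (table.upper_hu == -700)]
        assert cell.accuracy.iloc[0] == pytest.approx(direct.accuracy)
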