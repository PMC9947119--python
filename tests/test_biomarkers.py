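"""Classifier comparison, importance ranking, error curve, Cd correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhizomics import biomarkers as bm
from rhizomics import synthetic as syn
from rhizomics.containers import CdTable
from rhizomics.errors import InsufficientClassError, InvalidArgumentError


def planted_dimension_fixture(n=80, n_taxa=30, n_informative=6, log_fold=1.0, noise=0.8, seed=0):
    """Log-normal features with exactly ``n_informative`` class-shifted columns;
    the rest are pure noise (no compositional closure, so noise columns carry
    no class signal)."""
    rng = np.random.default_rng(seed)
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    mu = rng.normal(0, 1.0, n_taxa)
    eff = np.zeros(n_taxa)
    eff[:n_informative] = log_fold
    x = np.exp(mu + (y == "B")[:, None] * eff + rng.normal(0, noise, (n, n_taxa)))
    return pd.DataFrame(x, columns=[f"ASV{j:03d}" for j in range(n_taxa)]), y


def true_ranking(features: pd.DataFrame) -> pd.DataFrame:
    """Oracle importance ranking: column order is the planted order."""
    return pd.DataFrame(
        {
            "taxon": list(features.columns),
            "mda": np.linspace(1.0, 0.0, features.shape[1]),
            "rank": np.arange(1, features.shape[1] + 1),
        }
    )


def separable_fixture(n=54, n_taxa=40, n_informative=10, log_fold=4.0, noise=0.6, seed=0):
    """Two-class compositional data with planted informative taxa."""
    rng = np.random.default_rng(seed)
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    mu = rng.normal(0, 1.0, n_taxa)
    x = np.zeros((n, n_taxa))
    for i in range(n):
        eff = np.zeros(n_taxa)
        if y[i] == "B":
            eff[:n_informative] = log_fold
        w = np.exp(mu + eff + rng.normal(0, noise, n_taxa))
        x[i] = rng.multinomial(2000, w / w.sum())
    features = pd.DataFrame(x, columns=[f"ASV{j:03d}" for j in range(n_taxa)])
    return features.div(features.sum(axis=1), axis=0), y


class TestSplitData:
    def test_stratified_seventy_thirty(self):
        x, y = separable_fixture()
        split = bm.split_data(x, y, seed=0)
        assert len(split.x_train) in (37, 38)
        assert len(split.x_train) + len(split.x_test) == 54
        _, counts = np.unique(split.y_train, return_counts=True)
        assert abs(counts[0] - counts[1]) <= 1

    def test_partition_contract(self):
        x, y = separable_fixture()
        split = bm.split_data(x, y, seed=3)
        train_idx = set(split.x_train.index)
        test_idx = set(split.x_test.index)
        assert train_idx | test_idx == set(x.index)
        assert not (train_idx & test_idx)

    def test_deterministic(self):
        x, y = separable_fixture()
        a = bm.split_data(x, y, seed=5)
        b = bm.split_data(x, y, seed=5)
        assert list(a.x_train.index) == list(b.x_train.index)

    def test_single_class_rejected(self):
        x, _ = separable_fixture()
        with pytest.raises(InsufficientClassError):
            bm.split_data(x, ["A"] * len(x), seed=0)


class TestEvaluateModels:
    def test_separable_data_easily_classified(self):
        x, y = separable_fixture()
        models = bm.default_models(0, n_trees=100)
        evals, best = bm.evaluate_models(x, y, models=models, seed=0)
        best_err = min(e.average_error for e in evals)
        assert best_err <= 0.05
        assert best in bm.MODEL_ORDER

    def test_permuted_labels_near_chance(self):
        x, y = separable_fixture(seed=4)
        rng = np.random.default_rng(1)
        y_perm = rng.permutation(y)
        models = bm.default_models(0, n_trees=100)
        evals, _ = bm.evaluate_models(x, y_perm, models=models, seed=0)
        for e in evals:
            assert 0.30 <= e.average_error <= 0.70

    def test_folds_shared_and_deterministic(self):
        y = np.array(["A", "B"] * 15)
        f1 = bm._shared_folds(y, 5, seed=2)
        f2 = bm._shared_folds(y, 5, seed=2)
        for (tr1, va1), (tr2, va2) in zip(f1, f2):
            assert np.array_equal(tr1, tr2) and np.array_equal(va1, va2)
            assert np.unique(y[tr1]).size == 2


class TestImportance:
    def test_constant_feature_has_no_importance(self):
        x, y = separable_fixture()
        x = x.copy()
        x["ASV_FLAT"] = 0.01
        rank = bm.rf_importance(x, y, n_trees=60, n_repeats=5, seed=0)
        flat = rank.set_index("taxon").loc["ASV_FLAT", "mda"]
        assert abs(flat) < 0.01

    def test_planted_taxa_fill_top_ranks(self):
        x, y = separable_fixture(n_informative=5)
        rank = bm.rf_importance(x, y, n_trees=100, n_repeats=8, seed=1)
        top10 = set(rank.head(10)["taxon"])
        planted = {f"ASV{j:03d}" for j in range(5)}
        assert planted <= top10

    def test_duplicated_informative_feature_shares_importance(self):
        # single moderate-signal feature: duplication splits the trees between
        # the copies, so each copy's permutation costs some ensemble accuracy
        x, y = separable_fixture(n_informative=1, log_fold=1.5, noise=0.8)
        x = x.copy()
        x["ASV_DUP"] = x["ASV000"] * (1 + 1e-9)
        rank = bm.rf_importance(x, y, n_trees=100, n_repeats=8, seed=2).set_index("taxon")
        assert rank.loc["ASV000", "mda"] > 0
        assert rank.loc["ASV_DUP", "mda"] > 0

    def test_ranks_are_permutation(self):
        x, y = separable_fixture()
        rank = bm.rf_importance(x, y, n_trees=50, n_repeats=3, seed=0)
        assert sorted(rank["rank"]) == list(range(1, x.shape[1] + 1))


class TestErrorCurve:
    def test_full_feature_set_consistent_with_model_comparison(self):
        x, y = separable_fixture()
        models = bm.default_models(0, n_trees=100)
        evals, best = bm.evaluate_models(x, y, models=models, seed=0)
        best_err = next(e.average_error for e in evals if e.model == best)
        rank = bm.rf_importance(x, y, n_trees=60, n_repeats=5, seed=0)
        report = bm.cv_error_curve(
            x, y, rank, best_model=best, k_grid=[x.shape[1]], seed=0, models=models
        )
        assert report.curve["cv_error"].iloc[0] == pytest.approx(best_err, abs=0.05)

    def test_curve_values_bounded_and_selection_consistent(self):
        x, y = separable_fixture()
        models = bm.default_models(0, n_trees=60)
        rank = bm.rf_importance(x, y, n_trees=60, n_repeats=5, seed=0)
        report = bm.cv_error_curve(
            x, y, rank, best_model="RF", k_grid=range(1, 8), seed=0, models=models
        )
        assert report.curve["cv_error"].between(0, 1).all()
        best = report.curve["cv_error"].min()
        assert report.selected_k == report.curve.loc[report.curve["cv_error"] == best, "k"].min()
        assert len(report.biomarkers) == report.selected_k

    def test_empty_k_grid_rejected(self):
        x, y = separable_fixture()
        rank = bm.rf_importance(x, y, n_trees=30, n_repeats=2, seed=0)
        with pytest.raises(InvalidArgumentError):
            bm.cv_error_curve(x, y, rank, best_model="RF", k_grid=[], seed=0)


class TestFinalConfusion:
    def test_separable_confusion_near_diagonal(self):
        x, y = separable_fixture()
        split = bm.split_data(x, y, seed=0)
        models = bm.default_models(0, n_trees=100)
        ev = bm.final_confusion(split, "RF", list(x.columns[:10]), seed=0, models=models)
        cm = ev.confusion
        assert ev.overall_accuracy == pytest.approx(np.trace(cm) / cm.sum())
        for i, cls in enumerate(sorted(set(y))):
            assert ev.per_class_accuracy[cls] == pytest.approx(cm[i, i] / cm[i].sum())
        assert ev.overall_accuracy >= 0.9


class TestCdOperations:
    def test_zscore_unit_example(self):
        assert np.allclose(bm.zscore([1, 2, 3]), [-1, 0, 1])

    def test_zscore_flat_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bm.zscore([2, 2, 2])

    def test_spearman_invariant_under_zscore(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=25)
        b = 0.5 * a + rng.normal(0, 0.2, 25)
        raw = stats.spearmanr(a, b).statistic
        z = stats.spearmanr(bm.zscore(a), b).statistic
        assert raw == pytest.approx(z)

    def test_planted_cd_link_recovered(self):
        design = syn.StudyDesign(
            n_treatments=5, n_replicates=3, niches=("bulk", "rhizosphere"),
            n_taxa=40, depth_mean=800, seed=3,
        )
        truth = syn.default_truth(design, cd_coefficient=0.3)
        matrix, meta = syn.generate_communities(design, truth)
        cd = syn.generate_cd_measurements(design, truth, matrix, meta)
        out = bm.biomarker_cd_correlation(
            sorted(truth.cd_link), matrix, meta, cd, niche="rhizosphere"
        )
        joint = stats.combine_pvalues(out["p"])[1]
        assert (out["rho"] > 0).mean() >= 0.6
        assert joint < 0.05

    def test_bioaccumulation_factor_arithmetic(self):
        table = pd.DataFrame(
            {
                "cultivar": ["XS14", "YY17"],
                "treatment": ["CK", "CK"],
                "replicate": [1, 1],
                "grain_cd": [0.2, 0.0],
                "soil_total_cd": [0.4, 0.5],
                "soil_available_cd": [0.1, 0.1],
            }
        )
        baf = bm.bioaccumulation_factor(CdTable(table=table))
        assert baf.iloc[0] == pytest.approx(0.5)
        assert baf.iloc[1] == pytest.approx(0.0)

    def test_bioaccumulation_scale_invariance(self):
        t = pd.DataFrame(
            {
                "cultivar": ["XS14"], "treatment": ["CK"], "replicate": [1],
                "grain_cd": [0.3], "soil_total_cd": [0.6], "soil_available_cd": [0.2],
            }
        )
        a = bm.bioaccumulation_factor(CdTable(table=t))
        t2 = t.copy()
        t2[["grain_cd", "soil_total_cd"]] *= 1000  # mg/kg -> ug/kg
        b = bm.bioaccumulation_factor(CdTable(table=t2))
        assert a.iloc[0] == pytest.approx(b.iloc[0])

    def test_zero_soil_cd_rejected(self):
        t = pd.DataFrame(
            {
                "cultivar": ["XS14"], "treatment": ["CK"], "replicate": [1],
                "grain_cd": [0.3], "soil_total_cd": [0.0], "soil_available_cd": [0.2],
            }
        )
        with pytest.raises(InvalidArgumentError):
            bm.bioaccumulation_factor(CdTable(table=t))
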