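"""Cross-validated biomarker selection for cultivar classification.

Six classifiers (single-hidden-layer ANN, decision tree, random forest,
KNN, logistic regression, radial-kernel SVM) are compared by stratified
five-fold CV error on a 70/30 stratified split of per-niche relative
abundances; the best model's permutation importance (mean decrease
accuracy) ranks taxa, a CV error curve over the top-k features picks the
minimal biomarker set, performance is confirmed on the held-out test set,
and top biomarkers are correlated (Spearman, on Z-scored abundances) with
grain Cd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .containers import CdTable, CommunityMatrix
from .errors import InsufficientClassError, InvalidArgumentError

MODEL_ORDER = ("ANN", "DT", "RF", "KNN", "LR", "SVM")


def default_models(seed: int = 0, n_trees: int = 500) -> dict[str, object]:
    """The six classifier family with fixed, documented hyperparameters."""
    return {
        "ANN": MLPClassifier(hidden_layer_sizes=(16,), max_iter=2000, random_state=seed),
        "DT": DecisionTreeClassifier(random_state=seed),
        "RF": RandomForestClassifier(n_estimators=n_trees, random_state=seed),
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "LR": LogisticRegression(max_iter=5000),
        "SVM": SVC(kernel="rbf", gamma="scale", random_state=seed),
    }


# ---------------------------------------------------------------------------
# split and CV model comparison
# ---------------------------------------------------------------------------

@dataclass
class DataSplit:
    x_train: pd.DataFrame
    x_test: pd.DataFrame
    y_train: np.ndarray
    y_test: np.ndarray


def split_data(features: pd.DataFrame, labels, train_fraction: float = 0.7, seed: int = 0) -> DataSplit:
    """Stratified train/test split preserving class proportions."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise InsufficientClassError("need two classes")
    if (counts < 2).any():
        bad = [str(c) for c, n in zip(classes, counts) if n < 2]
        raise InsufficientClassError(f"classes with < 2 samples: {bad}")
    x_train, x_test, y_train, y_test = train_test_split(
        features, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    return DataSplit(x_train=x_train, x_test=x_test, y_train=y_train, y_test=y_test)


@dataclass
class ModelEvaluation:
    model: str
    fold_errors: list[float]
    average_error: float
    confusion: np.ndarray | None = None
    per_class_accuracy: dict[str, float] = field(default_factory=dict)
    overall_accuracy: float | None = None


def _shared_folds(y: np.ndarray, k_folds: int, seed: int, max_refold: int = 20):
    """Stratified folds shared across all models; refold (new seed, logged)
    if a training fold would see a single class."""
    for attempt in range(max_refold):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        ok = all(np.unique(y[tr]).size >= 2 for tr, _ in folds)
        if ok:
            if attempt:
                warnings.warn(f"refolded {attempt} time(s) to keep both classes per fold")
            return folds
    raise InsufficientClassError("could not build folds with both classes present")


def evaluate_models(
    x: pd.DataFrame,
    y,
    models: dict[str, object] | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[list[ModelEvaluation], str]:
    """Stratified k-fold CV error per model on the training data.

    All models see identical fold assignments.  Returns the evaluations and
    the best model name (lowest average error; ties resolved by the fixed
    order ANN, DT, RF, KNN, LR, SVM).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < k_folds).any():
        raise InsufficientClassError(f"every class needs >= {k_folds} training samples")
    if models is None:
        models = default_models(seed)
    folds = _shared_folds(y, k_folds, seed)
    xv = x.to_numpy()
    evals = []
    for name in MODEL_ORDER:
        if name not in models:
            continue
        errors = []
        for tr, va in folds:
            est = clone(models[name])
            est.fit(xv[tr], y[tr])
            errors.append(1.0 - accuracy_score(y[va], est.predict(xv[va])))
        evals.append(
            ModelEvaluation(model=name, fold_errors=errors, average_error=float(np.mean(errors)))
        )
    best = min(evals, key=lambda e: (e.average_error, MODEL_ORDER.index(e.model)))
    return evals, best.model


# ---------------------------------------------------------------------------
# importance ranking (mean decrease accuracy)
# ---------------------------------------------------------------------------

def rf_importance(
    x: pd.DataFrame,
    y,
    n_trees: int = 500,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance (MDA) from a random forest, held-out variant.

    Over ``n_repeats`` stratified 75/25 splits of the training data, a
    forest is fit on the sub-train part and each feature column is permuted
    on the validation part; MDA is the mean accuracy drop.  Ties in the
    descending ranking break by taxon id.
    """
    y = np.asarray(y)
    xv = x.to_numpy()
    rng = np.random.default_rng(seed)
    sss = StratifiedShuffleSplit(n_splits=n_repeats, test_size=0.25, random_state=seed)
    drops = np.zeros((n_repeats, xv.shape[1]))
    for r, (tr, va) in enumerate(sss.split(xv, y)):
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed + r)
        forest.fit(xv[tr], y[tr])
        base = accuracy_score(y[va], forest.predict(xv[va]))
        for j in range(xv.shape[1]):
            xp = xv[va].copy()
            xp[:, j] = xp[rng.permutation(len(va)), j]
            drops[r, j] = base - accuracy_score(y[va], forest.predict(xp))
    mda = drops.mean(axis=0)
    out = pd.DataFrame({"taxon": list(x.columns), "mda": mda})
    out = out.sort_values(["mda", "taxon"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CV error curve over top-k features
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerReport:
    niche: str
    best_model: str
    curve: pd.DataFrame  # columns k, cv_error
    selected_k: int
    biomarkers: list[str]
    cd_correlations: pd.DataFrame | None = None
    test_evaluation: ModelEvaluation | None = None


def default_k_grid(n_features: int) -> list[int]:
    """1..30 then every 5th feature up to 100 (capped at n_features)."""
    grid = list(range(1, min(30, n_features) + 1))
    grid += list(range(35, min(100, n_features) + 1, 5))
    return sorted(set(k for k in grid if 1 <= k <= n_features))


def cv_error_curve(
    x: pd.DataFrame,
    y,
    ranking: pd.DataFrame,
    best_model: str = "RF",
    k_grid=None,
    k_folds: int = 5,
    seed: int = 0,
    models: dict[str, object] | None = None,
    niche: str = "all",
    n_repeats: int = 1,
) -> BiomarkerReport:
    """Refit the best model on top-k ranked features for each k on the grid.

    selected_k is the smallest k attaining the minimum CV error; the
    biomarker set is the top selected_k ranked taxa.  ``n_repeats`` averages
    the error over repeated seeded k-fold splits, which smooths the curve's
    plateau so the minimum is not set by single-split noise.
    """
    ranked = list(ranking.sort_values("rank")["taxon"])
    if set(ranked) != set(x.columns):
        raise InvalidArgumentError("ranking must cover exactly the feature set")
    if k_grid is None:
        k_grid = default_k_grid(len(ranked))
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid or k_grid[0] < 1 or k_grid[-1] > len(ranked):
        raise InvalidArgumentError("k_grid must be a non-empty subset of 1..n_features")
    if models is None:
        models = default_models(seed)
    template = models[best_model]
    y = np.asarray(y)
    fold_sets = [_shared_folds(y, k_folds, seed + 1000 * rep) for rep in range(n_repeats)]

    rows = []
    for k in k_grid:
        cols = ranked[:k]
        xv = x[cols].to_numpy()
        errs = []
        for folds in fold_sets:
            for tr, va in folds:
                est = clone(template)
                est.fit(xv[tr], y[tr])
                errs.append(1.0 - accuracy_score(y[va], est.predict(xv[va])))
        rows.append((k, float(np.mean(errs))))
    curve = pd.DataFrame(rows, columns=["k", "cv_error"])
    best_err = curve["cv_error"].min()
    selected_k = int(curve.loc[curve["cv_error"] == best_err, "k"].min())
    return BiomarkerReport(
        niche=niche,
        best_model=best_model,
        curve=curve,
        selected_k=selected_k,
        biomarkers=ranked[:selected_k],
    )


# ---------------------------------------------------------------------------
# held-out confusion matrix
# ---------------------------------------------------------------------------

def final_confusion(
    split: DataSplit,
    best_model: str,
    biomarkers: list[str],
    seed: int = 0,
    models: dict[str, object] | None = None,
) -> ModelEvaluation:
    """Train the chosen model on training data (biomarker features only) and
    evaluate the 2x2 confusion matrix on the held-out test set."""
    if models is None:
        models = default_models(seed)
    est = clone(models[best_model])
    est.fit(split.x_train[biomarkers].to_numpy(), split.y_train)
    pred = est.predict(split.x_test[biomarkers].to_numpy())
    classes = np.unique(np.concatenate([split.y_train, split.y_test]))
    cm = confusion_matrix(split.y_test, pred, labels=classes)
    row_sums = cm.sum(axis=1)
    per_class = {
        str(c): (cm[i, i] / row_sums[i] if row_sums[i] else np.nan)
        for i, c in enumerate(classes)
    }
    return ModelEvaluation(
        model=best_model,
        fold_errors=[],
        average_error=float(1.0 - np.trace(cm) / cm.sum()),
        confusion=cm,
        per_class_accuracy=per_class,
        overall_accuracy=float(np.trace(cm) / cm.sum()),
    )


# ---------------------------------------------------------------------------
# biomarker-Cd correlation and bioaccumulation
# ---------------------------------------------------------------------------

def zscore(x) -> np.ndarray:
    """(x - mean) / sd with the sample (ddof=1) standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise InvalidArgumentError("zero-variance vector")
    return (x - x.mean()) / sd


def biomarker_cd_correlation(
    biomarkers: list[str],
    matrix: CommunityMatrix,
    metadata: pd.DataFrame,
    cd: CdTable,
    niche: str | None = None,
) -> pd.DataFrame:
    """Spearman correlation of Z-scored biomarker relative abundance vs grain Cd.

    Samples are joined to Cd measurements at the plot level (cultivar x
    treatment x replicate), averaging samples within a plot.  Zero-variance
    taxa are skipped with a warning.
    """
    meta = metadata.copy()
    if niche is not None:
        meta = meta[meta["niche"] == niche]
    rel = matrix.relative_abundance()
    merged = meta.merge(cd.table, on=["cultivar", "treatment", "replicate"], how="inner")
    if merged.empty:
        raise InvalidArgumentError("no samples map to Cd measurements")
    rows = []
    for taxon in biomarkers:
        per_plot = (
            merged.assign(abund=rel.loc[merged["sample_id"], taxon].to_numpy())
            .groupby(["cultivar", "treatment", "replicate"])
            .agg(abund=("abund", "mean"), grain_cd=("grain_cd", "first"))
            .reset_index()
        )
        if per_plot["abund"].std(ddof=1) == 0:
            warnings.warn(f"taxon {taxon!r} has zero variance; skipped")
            continue
        z = zscore(per_plot["abund"])
        rho, p = stats.spearmanr(z, per_plot["grain_cd"])
        rows.append((taxon, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["taxon", "rho", "p"])


def bioaccumulation_factor(cd: CdTable) -> pd.Series:
    """Grain Cd / bulk-soil total Cd, per plot."""
    soil = cd.table["soil_total_cd"]
    if (soil <= 0).any():
        raise InvalidArgumentError("soil total Cd must be positive")
    return (cd.table["grain_cd"] / soil).rename("bioaccumulation_factor")


# ---------------------------------------------------------------------------
# per-niche workflow
# ---------------------------------------------------------------------------

def run_biomarker_workflow(
    matrix: CommunityMatrix,
    metadata: pd.DataFrame,
    niche: str,
    cd: CdTable | None = None,
    seed: int = 0,
    k_folds: int = 5,
    k_grid=None,
    models: dict[str, object] | None = None,
    n_trees: int = 500,
    n_top_cd: int = 2,
) -> tuple[BiomarkerReport, list[ModelEvaluation]]:
    """split -> model comparison -> MDA ranking -> error curve -> confusion.

    Features are per-niche relative abundances at the taxon level; the label
    is the cultivar.
    """
    meta = metadata[metadata["niche"] == niche]
    ids = list(meta["sample_id"])
    sub = matrix.subset_samples(ids).drop_empty_taxa()
    features = sub.relative_abundance()
    labels = meta.set_index("sample_id").loc[features.index, "cultivar"].to_numpy()

    split = split_data(features, labels, seed=seed)
    evals, best = evaluate_models(split.x_train, split.y_train, models=models, k_folds=k_folds, seed=seed)
    ranking = rf_importance(split.x_train, split.y_train, n_trees=n_trees, seed=seed)
    report = cv_error_curve(
        split.x_train, split.y_train, ranking,
        best_model=best, k_grid=k_grid, k_folds=k_folds, seed=seed, models=models, niche=niche,
    )
    report.test_evaluation = final_confusion(split, best, report.biomarkers, seed=seed, models=models)
    if cd is not None:
        top = report.biomarkers[:n_top_cd]
        report.cd_correlations = biomarker_cd_correlation(top, matrix, metadata, cd, niche=niche)
    return report, evals
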