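"""Repeated-random-split machine learning on the feature table.

Two protocols:

* **Semiquantitative** — SNE binned into low / medium / high enhancement
  classes; a multinomial logistic regression is refit over many random
  stratified train/test splits and every test prediction is accumulated
  into one cumulative confusion matrix. Repeating the split is essential
  at this data size: a single split's confusion matrix is dominated by
  which of the handful of high-SNE sites landed in the test set.

* **Quantitative** — several regressors (k-NN, gradient-boosted trees,
  random forest, ridge, SVR) each trained over repeated
  train/validation/test splits with a small per-model hyperparameter grid
  tuned on the validation fold; test-fold R^2 / RMSE / MAE are averaged
  and feature importances (native gain for tree models, permutation
  importance otherwise) are averaged across runs.

All standardization is fit on the training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .config import PipelineConfig
from .records import FEATURE_COLUMNS, FeatureTable

CLASS_LABELS = ("low", "medium", "high")


def classify_sne(sne, thresholds: tuple[float, float] = (40.0, 90.0)):
    """Bin SNE into low / medium / high enhancement classes.

    Boundary values fall into the medium class (the strict inequalities
    defining low and high leave the boundaries unassigned; closing medium
    is the symmetric choice). Vectorized over array input.
    """
    low_upper, high_lower = thresholds
    arr = np.asarray(sne, dtype=float)
    if (arr < 0).any():
        raise ValueError("sne must be non-negative")
    out = np.where(arr < low_upper, "low", np.where(arr > high_lower, "high", "medium"))
    return out if out.ndim else str(out)


@dataclass
class CumulativeConfusion:
    """Row-normalized confusion fractions accumulated over many splits."""

    matrix: pd.DataFrame  # rows = true class, columns = predicted, fractions
    counts: pd.DataFrame  # raw accumulated counts
    n_runs: int
    n_resampled: int
    per_class_support: dict[str, int]

    def diagonal(self) -> dict[str, float]:
        return {c: float(self.matrix.at[c, c]) for c in self.matrix.index}


def repeated_split_classification(
    table: FeatureTable,
    n_runs: int | None = None,
    train_fraction: float | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> tuple[CumulativeConfusion, pd.Series]:
    """Repeated stratified-split logistic classification of SNE classes.

    Per run: stratified random train/test split, z-scoring fitted on the
    training fold, multinomial logistic regression, and test predictions
    added to the cumulative confusion matrix under their true class.
    Returns the confusion summary and feature importances (mean absolute
    standardized coefficient per feature, normalized to sum 1).
    Deterministic for a fixed seed. Splits that lose a class from the
    training fold are resampled and counted.
    """
    config = config or PipelineConfig()
    n_runs = n_runs if n_runs is not None else config.n_class_runs
    train_fraction = train_fraction if train_fraction is not None else config.class_train_fraction
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(config.child_seed("classify") if seed is None else seed)

    X = table.features().to_numpy(dtype=float)
    y = classify_sne(table.frame["sne"].to_numpy(dtype=float), config.class_thresholds)
    present = [c for c in CLASS_LABELS if (y == c).sum() > 0]
    support = {c: int((y == c).sum()) for c in present}
    thin = [c for c, n in support.items() if n < 2]
    if thin:
        raise ValueError(f"class(es) with fewer than 2 members: {thin}")

    counts = pd.DataFrame(0.0, index=present, columns=present)
    coef_acc = np.zeros(X.shape[1])
    n_resampled = 0
    for _ in range(n_runs):
        while True:
            split_seed = int(rng.integers(2**31))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, train_size=train_fraction, stratify=y, random_state=split_seed
            )
            if set(np.unique(y_tr)) == set(present) and len(y_te) > 0:
                break
            n_resampled += 1
        scaler = StandardScaler().fit(X_tr)
        clf = LogisticRegression(max_iter=1000).fit(scaler.transform(X_tr), y_tr)
        pred = clf.predict(scaler.transform(X_te))
        for t, p in zip(y_te, pred):
            counts.at[t, p] += 1
        coef_acc += np.abs(clf.coef_).mean(axis=0)

    matrix = counts.div(counts.sum(axis=1), axis=0)
    importances = pd.Series(coef_acc / coef_acc.sum(), index=list(FEATURE_COLUMNS), name="importance")
    return (
        CumulativeConfusion(matrix, counts, n_runs, n_resampled, support),
        importances,
    )


# ---------------------------------------------------------------------------
# regression suite
# ---------------------------------------------------------------------------

#: Model roster with the small, fixed hyperparameter grids tuned on the
#: validation fold. "gbrt" is scikit-learn's gradient-boosted decision
#: trees (named in every report).
MODEL_REGISTRY: dict[str, tuple[type, dict[str, list]]] = {
    "knn": (KNeighborsRegressor, {"n_neighbors": [3, 5, 7]}),
    "gbrt": (GradientBoostingRegressor, {"n_estimators": [100, 300], "max_depth": [2, 3]}),
    "random_forest": (RandomForestRegressor, {"n_estimators": [200], "max_depth": [None, 4]}),
    "ridge": (Ridge, {"alpha": [0.1, 1.0, 10.0]}),
    "svr": (SVR, {"C": [1.0, 10.0, 100.0]}),
}
TREE_MODELS = ("gbrt", "random_forest")


@dataclass
class EvaluationReport:
    """Per-model summary of a repeated-split regression evaluation."""

    model_name: str
    implementation: str
    per_run_scores: pd.DataFrame  # columns r2, rmse, mae — test fold only
    mean_scores: dict[str, float]
    std_scores: dict[str, float]
    composite_score: float  # mean test R^2
    importances: pd.Series = field(repr=False)  # normalized to sum 1


def performance_score(y_true, y_pred) -> dict[str, float]:
    """Test-fold performance metrics: R^2 (primary), RMSE, MAE.

    The composite score reported per model is the mean test R^2 across
    runs; RMSE and MAE are carried alongside.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    return {
        "r2": float(r2_score(y_true, y_pred)),
        "rmse": float(np.sqrt(mean_squared_error(y_true, y_pred))),
        "mae": float(mean_absolute_error(y_true, y_pred)),
    }


def _grid(params: dict[str, list]) -> list[dict]:
    keys = list(params)
    return [dict(zip(keys, combo)) for combo in product(*params.values())]


def _make_model(cls, params: dict, seed: int):
    if "random_state" in cls().get_params():
        return cls(**params, random_state=seed)
    return cls(**params)


def repeated_split_regression(
    table: FeatureTable,
    models: list[str] | None = None,
    n_runs: int | None = None,
    fractions: tuple[float, float, float] | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> list[EvaluationReport]:
    """Evaluate the regressor suite over repeated train/val/test splits.

    Per run and model: split by ``fractions``, z-score on the training
    fold, pick the grid point with the best validation R^2, then score on
    the held-out test fold. Importances are the model's native impurity
    gain for tree models and test-fold permutation importance for the
    rest; negative permutation values are floored at zero before the
    across-run average is normalized. Reports are sorted by composite
    score, best first.
    """
    config = config or PipelineConfig()
    models = models or list(MODEL_REGISTRY)
    unknown = [m for m in models if m not in MODEL_REGISTRY]
    if unknown:
        raise ValueError(f"unknown model(s) {unknown}; supported: {sorted(MODEL_REGISTRY)}")
    n_runs = n_runs if n_runs is not None else config.n_regress_runs
    fractions = fractions if fractions is not None else config.regress_fractions
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(config.child_seed("regress") if seed is None else seed)

    X = table.features().to_numpy(dtype=float)
    y = table.frame["sne"].to_numpy(dtype=float)
    f_tr, f_va, f_te = fractions
    n = len(y)
    if min(int(n * f) for f in fractions) < 2:
        raise ValueError(f"table too small ({n} rows) for fractions {fractions}")

    scores: dict[str, list[dict]] = {m: [] for m in models}
    imp_acc = {m: np.zeros(X.shape[1]) for m in models}
    for _ in range(n_runs):
        run_seed = int(rng.integers(2**31))
        X_tr, X_rest, y_tr, y_rest = train_test_split(
            X, y, train_size=f_tr, random_state=run_seed
        )
        X_va, X_te, y_va, y_te = train_test_split(
            X_rest, y_rest, train_size=f_va / (f_va + f_te), random_state=run_seed + 1
        )
        scaler = StandardScaler().fit(X_tr)
        Xs_tr, Xs_va, Xs_te = map(scaler.transform, (X_tr, X_va, X_te))

        for name in models:
            cls, grid = MODEL_REGISTRY[name]
            best, best_val = None, -np.inf
            for params in _grid(grid):
                model = _make_model(cls, params, run_seed).fit(Xs_tr, y_tr)
                val = r2_score(y_va, model.predict(Xs_va))
                if val > best_val:
                    best, best_val = model, val
            scores[name].append(performance_score(y_te, best.predict(Xs_te)))
            if name in TREE_MODELS:
                imp = np.asarray(best.feature_importances_, dtype=float)
            else:
                perm = permutation_importance(
                    best, Xs_te, y_te, n_repeats=5, random_state=run_seed
                )
                imp = np.clip(perm.importances_mean, 0.0, None)
            total = imp.sum()
            imp_acc[name] += imp / total if total > 0 else 0.0

    reports = []
    for name in models:
        per_run = pd.DataFrame(scores[name])
        imp = imp_acc[name] / n_runs
        imp = imp / imp.sum() if imp.sum() > 0 else imp
        reports.append(
            EvaluationReport(
                model_name=name,
                implementation=MODEL_REGISTRY[name][0].__name__,
                per_run_scores=per_run,
                mean_scores={k: float(per_run[k].mean()) for k in per_run},
                std_scores={k: float(per_run[k].std(ddof=1)) if len(per_run) > 1 else 0.0 for k in per_run},
                composite_score=float(per_run["r2"].mean()),
                importances=pd.Series(imp, index=list(FEATURE_COLUMNS), name=name),
            )
        )
    reports.sort(key=lambda r: r.composite_score, reverse=True)
    return reports
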