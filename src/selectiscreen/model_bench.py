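"""Classifier benchmarking: grid-search CV, the seven-metric suite, ROC/AUC,
TOPSIS ranking, and probability screening.

Eight classifier families are benchmarked: decision tree (DT), k-nearest
neighbors (kNN), support vector machine (SVM), random forest (RF), extremely
randomized trees (ERT), AdaBoost, gradient boosted trees (GBT) and XGBoost.
Learner training is delegated to scikit-learn/xgboost behind a fit /
predict-probability contract; the procedure this module owns is the
stratified split, the grid search over 10-fold cross-validated accuracy, the
metric suite computed from the confusion matrix, the rank-based AUC, the
TOPSIS multi-criteria ranking, and the probability screen.

Metric definitions (tp/fp/tn/fn from the confusion matrix, total = sum):

    accuracy    = (tp + tn) / total
    sensitivity = tp / (tp + fn)            (recall of the active class)
    specificity = tn / (tn + fp)
    precision   = tp / (tp + fp)
    f1          = harmonic mean of precision and sensitivity
    kappa       = (p_o - p_e) / (1 - p_e), p_e from the marginals
    mcc         = (tp tn - fp fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))

AUC uses the rank (Mann-Whitney) formulation with ties contributing 1/2.
TOPSIS vector-normalizes each criterion column, weights it, and scores each
model by closeness d-/(d+ + d-) to the ideal point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .chem_data import DescriptorMatrix, SchemaError

MODEL_FAMILIES = ("DT", "kNN", "SVM", "RF", "ERT", "AdaBoost", "GBT", "XGBoost")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionMatrix":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
        )


#: criterion names in the fixed order used by the seven-metric suite
METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "kappa", "mcc")


@dataclass
class MetricVector:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    kappa: float
    mcc: float
    auc: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)  # metric -> reason

    def as_dict(self, include_auc: bool = True) -> dict[str, float]:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        if include_auc and self.auc is not None:
            d["auc"] = self.auc
        return d


def compute_metrics(cm: ConfusionMatrix) -> MetricVector:
    """Compute the seven-metric suite from a confusion matrix.

    Metrics with an undefined denominator are reported as NaN with the reason
    recorded in ``undefined``.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    total = cm.total
    undefined: dict[str, str] = {}

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined[name] = "zero denominator"
            return math.nan
        return num / den

    accuracy = (tp + tn) / total
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")

    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        undefined["f1"] = "precision + sensitivity is zero or undefined"
        f1 = math.nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)

    # Cohen's kappa from marginals
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (total * total)
    if pe == 1.0:
        undefined["kappa"] = "chance agreement is 1"
        kappa = math.nan
    else:
        kappa = (accuracy - pe) / (1.0 - pe)

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined["mcc"] = "a marginal count is zero"
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)

    return MetricVector(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        kappa=kappa,
        mcc=mcc,
        undefined=undefined,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the rank / Mann-Whitney formulation.

    Ties among scores contribute 1/2 per tied positive-negative pair.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2 contributions
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# model specifications and grid search


@dataclass
class ModelSpec:
    """A classifier family, its hyperparameter grid, and the chosen values."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    chosen_params: dict = field(default_factory=dict)
    estimator_: object | None = None  # fitted learner after fit()

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; known: {MODEL_FAMILIES}")


#: hyperparameters taken as the published optimization outcome for each family
DEFAULT_PARAMS: dict[str, dict] = {
    "DT": {"max_depth": 10},
    "kNN": {"n_neighbors": 5, "weights": "distance"},
    "SVM": {"C": 1.0},
    "RF": {"n_estimators": 200, "max_depth": 3},
    "ERT": {"n_estimators": 200, "max_depth": 3},
    "AdaBoost": {"n_estimators": 200, "max_depth": 5},
    "GBT": {"n_estimators": 200, "max_depth": 5},
    "XGBoost": {"n_estimators": 200, "max_depth": 5},
}

#: small default grids around the published values
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {"max_depth": [10, 5]},
    "kNN": {"n_neighbors": [5, 3], "weights": ["distance"]},
    "SVM": {"C": [1.0, 10.0]},
    "RF": {"n_estimators": [200], "max_depth": [3, 5]},
    "ERT": {"n_estimators": [200], "max_depth": [3, 5]},
    "AdaBoost": {"n_estimators": [200], "max_depth": [5]},
    "GBT": {"n_estimators": [200], "max_depth": [5, 3]},
    "XGBoost": {"n_estimators": [200], "max_depth": [5, 3]},
}


def build_estimator(family: str, params: Mapping | None = None, seed: int = 0):
    """Instantiate the underlying learner for a family with given params."""
    p = dict(DEFAULT_PARAMS[family])
    if params:
        p.update(params)
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed, **p)
    if family == "kNN":
        return KNeighborsClassifier(**p)
    if family == "SVM":
        # Platt-scaled probabilities for the margin classifier
        return CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed, **p), ensemble=False)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, **p)
    if family == "ERT":
        return ExtraTreesClassifier(random_state=seed, **p)
    if family == "AdaBoost":
        depth = p.pop("max_depth", 5)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=depth, random_state=seed),
            random_state=seed,
            **p,
        )
    if family == "GBT":
        return GradientBoostingClassifier(random_state=seed, **p)
    if family == "XGBoost":
        return XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
            n_jobs=1,
            **p,
        )
    raise ValueError(family)


def split_dataset(
    matrix: DescriptorMatrix, test_fraction: float = 0.2, seed: int = 0
) -> tuple[DescriptorMatrix, DescriptorMatrix]:
    """Stratified train/test split preserving class proportions within +/-1.

    The two parts are disjoint and exhaustive; the same seed yields the same
    split.

    Raises
    ------
    ValueError
        If labels are absent, a class is missing, or the fraction is not in
        (0, 1).
    """
    if matrix.labels is None:
        raise ValueError("split requires labels")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = matrix.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for a stratified split")
    ids = np.array(matrix.compound_ids)
    train_ids, test_ids = train_test_split(
        ids, test_size=test_fraction, stratify=y, random_state=seed
    )
    return matrix.subset_rows(list(train_ids)), matrix.subset_rows(list(test_ids))


def grid_search_cv(
    spec: ModelSpec, train: DescriptorMatrix, folds: int = 10, seed: int = 0
) -> ModelSpec:
    """Choose hyperparameters maximizing mean cross-validated accuracy.

    Ties go to the first combination in grid order.  The returned spec has
    ``chosen_params`` filled and a fitted estimator (refit on the full
    training set) in ``estimator_``, plus ``cv_accuracy_`` and ``cv_results_``
    attributes.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = spec.grid or DEFAULT_GRIDS[spec.family]
    x = train.values.to_numpy(dtype=float)
    y = train.labels.to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds with class counts {counts.tolist()}"
        )
    # grid keys that parameterize the wrapped base tree (AdaBoost) are handled
    # inside build_estimator, so search runs over a fresh estimator per combo
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    if spec.family == "AdaBoost":
        grid = {
            ("estimator__max_depth" if k == "max_depth" else k): v for k, v in grid.items()
        }
    elif spec.family == "SVM":
        # the SVC sits inside the probability-calibration wrapper
        grid = {f"estimator__{k}": v for k, v in grid.items()}
    search = GridSearchCV(
        build_estimator(spec.family, seed=seed),
        param_grid=grid,
        scoring="accuracy",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(x, y)
    chosen = {
        k.replace("estimator__", ""): v for k, v in search.best_params_.items()
    }
    out = ModelSpec(family=spec.family, grid=dict(spec.grid), chosen_params=chosen)
    out.estimator_ = search.best_estimator_
    out.cv_accuracy_ = float(search.best_score_)
    out.cv_results_ = search.cv_results_
    out.feature_names_ = list(train.values.columns)
    return out


def cross_val_auc(spec: ModelSpec, train: DescriptorMatrix, folds: int = 10, seed: int = 0) -> float:
    """Mean out-of-fold AUC of the chosen configuration over stratified folds."""
    x = train.values.to_numpy(dtype=float)
    y = train.labels.to_numpy()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in cv.split(x, y):
        est = build_estimator(spec.family, spec.chosen_params, seed=seed)
        est.fit(x[tr], y[tr])
        p = est.predict_proba(x[te])[:, 1]
        if len(np.unique(y[te])) == 2:
            aucs.append(roc_auc(p, y[te]))
    return float(np.mean(aucs))


@dataclass
class TopsisRanking:
    decision_matrix: pd.DataFrame
    weights: np.ndarray
    closeness: dict[str, float]
    ranking: list[str]


def topsis_rank(
    decision_matrix: pd.DataFrame,
    weights: Sequence[float] | None = None,
    directions: Sequence[str] | None = None,
) -> TopsisRanking:
    """Rank alternatives (rows) by TOPSIS closeness to the ideal solution.

    Columns are criteria; ``directions`` holds "benefit" or "cost" per column
    (all benefit by default, as for the seven classification metrics).
    Steps: vector-normalize each column, weight, take per-criterion ideal
    (best) and anti-ideal (worst) points, and score each row by
    closeness = d- / (d+ + d-).  A single alternative gets closeness 1 by
    convention (its d+ is 0).

    Raises
    ------
    ValueError
        On negative weights, an all-zero criterion column, or an unknown
        direction.
    """
    m = decision_matrix.to_numpy(dtype=float)
    n_alt, n_crit = m.shape
    if weights is None:
        w = np.full(n_crit, 1.0 / n_crit)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        w = w / w.sum()
    if directions is None:
        directions = ["benefit"] * n_crit
    if any(d not in ("benefit", "cost") for d in directions):
        raise ValueError("directions must be 'benefit' or 'cost'")

    norms = np.sqrt((m * m).sum(axis=0))
    if (norms == 0).any():
        bad = [decision_matrix.columns[i] for i in np.where(norms == 0)[0]]
        raise ValueError(f"all-zero criterion columns: {bad}")
    v = (m / norms) * w

    ideal = np.empty(n_crit)
    anti = np.empty(n_crit)
    for j, d in enumerate(directions):
        col = v[:, j]
        ideal[j] = col.max() if d == "benefit" else col.min()
        anti[j] = col.min() if d == "benefit" else col.max()

    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti) ** 2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        closeness = np.where(d_plus + d_minus == 0, 1.0, d_minus / (d_plus + d_minus))

    names = list(decision_matrix.index)
    order = sorted(range(n_alt), key=lambda i: (-closeness[i], names[i]))
    return TopsisRanking(
        decision_matrix=decision_matrix,
        weights=w,
        closeness={names[i]: float(closeness[i]) for i in range(n_alt)},
        ranking=[names[i] for i in order],
    )


def screen_library(
    model: ModelSpec, library: DescriptorMatrix, threshold: float = 0.5
) -> pd.DataFrame:
    """Score a compound library with a fitted model and label by probability.

    Returns a DataFrame indexed by compound id with ``probability`` and
    ``label`` columns; label = 1 iff probability >= threshold (boundary
    inclusive).

    Raises
    ------
    SchemaError
        If the library's columns do not match the model's training features.
    """
    if model.estimator_ is None:
        raise ValueError("model is not fitted")
    feats = getattr(model, "feature_names_", None)
    if feats is not None:
        missing = [f for f in feats if f not in library.values.columns]
        if missing:
            raise SchemaError(f"library is missing model features: {missing}")
        x = library.values.loc[:, feats].to_numpy(dtype=float)
    else:
        x = library.values.to_numpy(dtype=float)
    if len(library.values) == 0:
        return pd.DataFrame(columns=["probability", "label"], index=library.values.index)
    proba = model.estimator_.predict_proba(x)[:, 1]
    label = (proba >= threshold).astype(int)
    return pd.DataFrame(
        {"probability": proba, "label": label}, index=library.values.index
    )


@dataclass
class BenchResult:
    """Benchmark outcome: per-model test metrics, CV AUC, and TOPSIS ranking."""

    specs: dict[str, ModelSpec]
    metrics: dict[str, MetricVector]
    cv_auc: dict[str, float]
    topsis: TopsisRanking

    @property
    def best_model(self) -> str:
        return self.topsis.ranking[0]

    def metrics_frame(self) -> pd.DataFrame:
        rows = {name: mv.as_dict() for name, mv in self.metrics.items()}
        return pd.DataFrame(rows).T


def bench_models(
    train: DescriptorMatrix,
    test: DescriptorMatrix,
    families: Sequence[str] = MODEL_FAMILIES,
    folds: int = 10,
    seed: int = 0,
    topsis_weights: Sequence[float] | None = None,
) -> BenchResult:
    """Grid-search, fit and evaluate each family; rank by TOPSIS.

    The TOPSIS decision matrix holds the seven test-set metrics (all benefit
    criteria) per model, equal weights by default.
    """
    specs: dict[str, ModelSpec] = {}
    metrics: dict[str, MetricVector] = {}
    cv_auc: dict[str, float] = {}
    y_test = test.labels.to_numpy()
    for fam in families:
        spec = grid_search_cv(ModelSpec(family=fam), train, folds=folds, seed=seed)
        scored = screen_library(spec, test)
        cm = ConfusionMatrix.from_predictions(y_test, scored["label"].to_numpy())
        mv = compute_metrics(cm)
        mv.auc = roc_auc(scored["probability"].to_numpy(), y_test)
        specs[fam] = spec
        metrics[fam] = mv
        cv_auc[fam] = cross_val_auc(spec, train, folds=folds, seed=seed)

    decision = pd.DataFrame(
        {m: [metrics[f].as_dict(include_auc=False)[m] for f in families] for m in METRIC_NAMES},
        index=list(families),
    ).fillna(0.0)
    ranking = topsis_rank(decision, weights=topsis_weights)
    return BenchResult(specs=specs, metrics=metrics, cv_auc=cv_auc, topsis=ranking)
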