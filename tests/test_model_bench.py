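"""Metric suite, rank AUC, TOPSIS, splits, grid search and screening."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from selectiscreen import synthetic_data as sd
from selectiscreen.chem_data import SchemaError
from selectiscreen.feature_reduction import reduce_matrix
from selectiscreen.model_bench import (
    ConfusionMatrix,
    MetricVector,
    ModelSpec,
    compute_metrics,
    grid_search_cv,
    roc_auc,
    screen_library,
    split_dataset,
    topsis_rank,
)


# --- confusion-matrix metrics ------------------------------------------------

def test_perfect_classifier_all_metrics_one():
    mv = compute_metrics(ConfusionMatrix(tp=7, fp=0, tn=9, fn=0))
    for name in ("accuracy", "sensitivity", "specificity", "precision", "f1", "kappa", "mcc"):
        assert getattr(mv, name) == pytest.approx(1.0)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionMatrix(tp=-1, fp=0, tn=1, fn=0)


def test_undefined_denominators_reported_not_raised():
    mv = compute_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
    assert math.isnan(mv.sensitivity) and "sensitivity" in mv.undefined
    assert math.isnan(mv.precision) and "precision" in mv.undefined


@pytest.mark.parametrize("seed", range(6))
def test_metrics_match_recount_oracle(seed):
    """Metric formulas agree with a naive recount from random predictions,
    cross-checked against the reference statistics library."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, 40)
    yhat = rng.integers(0, 2, 40)
    if len(np.unique(y)) < 2 or len(np.unique(yhat)) < 2:
        y[0], y[1], yhat[0], yhat[1] = 0, 1, 0, 1
    cm = ConfusionMatrix.from_predictions(y, yhat)
    mv = compute_metrics(cm)
    from sklearn.metrics import (
        accuracy_score,
        cohen_kappa_score,
        f1_score,
        matthews_corrcoef,
        precision_score,
        recall_score,
    )

    assert mv.accuracy == pytest.approx(accuracy_score(y, yhat))
    assert mv.sensitivity == pytest.approx(recall_score(y, yhat))
    assert mv.precision == pytest.approx(precision_score(y, yhat))
    assert mv.f1 == pytest.approx(f1_score(y, yhat))
    assert mv.kappa == pytest.approx(cohen_kappa_score(y, yhat))
    assert mv.mcc == pytest.approx(matthews_corrcoef(y, yhat))


def test_diagonal_matrix_iff_unit_kappa_mcc_f1():
    mv = compute_metrics(ConfusionMatrix(tp=3, fp=1, tn=4, fn=0))
    assert mv.kappa < 1 and mv.mcc < 1 and mv.f1 < 1


# --- AUC ---------------------------------------------------------------------

def test_auc_perfect_ordering():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_auc_all_ties_is_half():
    assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


@pytest.mark.parametrize("seed", range(5))
def test_auc_matches_pairwise_enumeration(seed):
    """Rank-based AUC equals direct enumeration over all positive-negative
    pairs (ties counted 1/2) on small random score vectors."""
    rng = np.random.default_rng(seed)
    scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=10)
    labels = rng.integers(0, 2, 10)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    wins = total = 0.0
    for sp in scores[labels == 1]:
        for sn in scores[labels == 0]:
            total += 1
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    assert roc_auc(scores, labels) == pytest.approx(wins / total)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    scores = rng.random(30)
    labels = rng.integers(0, 2, 30)
    labels[:2] = [0, 1]
    a1 = roc_auc(scores, labels)
    a2 = roc_auc(np.exp(5 * scores), labels)
    assert a1 == pytest.approx(a2)


# --- TOPSIS ------------------------------------------------------------------

def test_topsis_single_alternative_closeness_one():
    dm = pd.DataFrame([[0.5, 0.7]], index=["only"], columns=["a", "b"])
    r = topsis_rank(dm)
    assert r.closeness["only"] == 1.0


def test_topsis_dominating_alternative_ranks_first():
    dm = pd.DataFrame([[0.9, 0.9], [0.5, 0.4], [0.2, 0.1]], index=["top", "mid", "low"],
                      columns=["a", "b"])
    r = topsis_rank(dm)
    assert r.ranking[0] == "top"
    assert r.closeness["top"] == pytest.approx(1.0)


def test_topsis_matches_hand_computation():
    """Closeness on a 3x2 matrix matches step-by-step arithmetic done
    independently of the implementation."""
    m = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
    # vector normalization
    norm = m / np.sqrt((m**2).sum(axis=0))
    v = norm * 0.5  # equal weights
    ideal = v.max(axis=0)
    anti = v.min(axis=0)
    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti) ** 2).sum(axis=1))
    expected = d_minus / (d_plus + d_minus)

    dm = pd.DataFrame(m, index=["A", "B", "C"], columns=["c1", "c2"])
    r = topsis_rank(dm, weights=[0.5, 0.5])
    for i, name in enumerate(["A", "B", "C"]):
        assert r.closeness[name] == pytest.approx(expected[i], abs=1e-12)
    order = np.argsort(-expected)
    assert r.ranking == [["A", "B", "C"][i] for i in order]


def test_topsis_scale_invariance():
    """Vector normalization makes the ranking invariant under positive
    rescaling of any criterion column."""
    rng = np.random.default_rng(4)
    m = rng.random((5, 3)) + 0.1
    dm1 = pd.DataFrame(m, index=list("abcde"))
    m2 = m.copy()
    m2[:, 1] *= 37.5
    dm2 = pd.DataFrame(m2, index=list("abcde"))
    r1, r2 = topsis_rank(dm1), topsis_rank(dm2)
    assert r1.ranking == r2.ranking
    for k in r1.closeness:
        assert r1.closeness[k] == pytest.approx(r2.closeness[k])


def test_topsis_negative_weights_rejected():
    dm = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ValueError, match="non-negative"):
        topsis_rank(dm, weights=[-1, 2])


def test_topsis_cost_direction():
    dm = pd.DataFrame([[1.0], [2.0]], index=["small", "big"], columns=["c"])
    assert topsis_rank(dm, directions=["cost"]).ranking[0] == "small"


# --- splits and grid search --------------------------------------------------

def test_split_proportions_on_study_sized_dataset(planted_factor_matrix):
    """An 80/20 stratified split of 300 compounds (151/149) puts 60 in the
    test set with 30 or 31 actives."""
    matrix, _ = planted_factor_matrix
    train, test = split_dataset(matrix, test_fraction=0.2, seed=0)
    assert test.n_compounds == 60 and train.n_compounds == 240
    assert int(test.labels.sum()) in (30, 31)
    assert set(train.compound_ids).isdisjoint(test.compound_ids)
    assert set(train.compound_ids) | set(test.compound_ids) == set(matrix.compound_ids)


def test_split_balanced_four():
    m = make_matrix(np.arange(8).reshape(4, 2), labels=[0, 1, 0, 1])
    train, test = split_dataset(m, test_fraction=0.5, seed=1)
    assert train.n_compounds == test.n_compounds == 2
    assert int(train.labels.sum()) == int(test.labels.sum()) == 1


def test_split_deterministic(planted_factor_matrix):
    matrix, _ = planted_factor_matrix
    a = split_dataset(matrix, seed=42)[1].compound_ids
    b = split_dataset(matrix, seed=42)[1].compound_ids
    assert a == b


def test_split_single_class_errors():
    m = make_matrix(np.arange(8).reshape(4, 2), labels=[1, 1, 1, 1])
    with pytest.raises(ValueError):
        split_dataset(m, test_fraction=0.5, seed=0)


def test_grid_single_combination_chosen(small_labeled_matrix):
    spec = ModelSpec(family="DT", grid={"max_depth": [4]})
    out = grid_search_cv(spec, small_labeled_matrix, folds=5, seed=0)
    assert out.chosen_params == {"max_depth": 4}
    assert out.estimator_ is not None


def test_grid_tie_break_first_in_order():
    """On separable data both kNN settings reach CV accuracy 1; the first
    grid entry wins the tie."""
    x = np.concatenate([np.zeros(20), np.ones(20) * 10]).reshape(-1, 1)
    x = x + np.linspace(0, 0.1, 40).reshape(-1, 1)
    m = make_matrix(x, labels=[0] * 20 + [1] * 20)
    spec = ModelSpec(family="kNN", grid={"n_neighbors": [1, 5], "weights": ["uniform"]})
    out = grid_search_cv(spec, m, folds=5, seed=0)
    assert out.chosen_params["n_neighbors"] == 1
    assert out.cv_accuracy_ == pytest.approx(1.0)


def test_cv_prefers_generalizing_depth():
    """Planted low-dimensional signal with label noise: exhaustive 2-point CV
    over tree depth must agree with the grid search's choice."""
    rng = np.random.default_rng(0)
    n = 120
    x = rng.standard_normal((n, 5))
    y = (x[:, 0] > 0).astype(int)
    flip = rng.random(n) < 0.25
    y[flip] = 1 - y[flip]
    m = make_matrix(x, labels=y)
    grid = {"max_depth": [2, 20]}
    out = grid_search_cv(ModelSpec(family="DT", grid=grid), m, folds=5, seed=0)
    # independent exhaustive CV over the same folds
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.tree import DecisionTreeClassifier

    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    means = {
        d: cross_val_score(
            DecisionTreeClassifier(max_depth=d, random_state=0), x, y, cv=cv,
            scoring="accuracy",
        ).mean()
        for d in grid["max_depth"]
    }
    best = max(grid["max_depth"], key=lambda d: means[d])
    assert out.chosen_params["max_depth"] == best


# --- screening ---------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_model(small_labeled_matrix):
    return grid_search_cv(
        ModelSpec(family="RF", grid={"n_estimators": [50], "max_depth": [3]}),
        small_labeled_matrix,
        folds=5,
        seed=0,
    )


def test_screen_boundary_probability_labeled_active(fitted_model, small_labeled_matrix):
    out = screen_library(fitted_model, small_labeled_matrix, threshold=0.0)
    assert (out["label"] == 1).all()  # every probability >= 0 -> inclusive boundary


def test_screen_empty_library(fitted_model, small_labeled_matrix):
    empty = small_labeled_matrix.subset_rows([])
    out = screen_library(fitted_model, empty)
    assert len(out) == 0


def test_screen_feature_mismatch_errors(fitted_model):
    bad = make_matrix(np.ones((3, 2)), names=["foo", "bar"])
    with pytest.raises(SchemaError, match="missing model features"):
        screen_library(fitted_model, bad)


def test_screen_recovers_generator_active_fraction():
    """A model trained on the generator's label model recovers the designed
    active fraction on a fresh library, within binomial error."""
    cfg = sd.GeneratorConfig(seed=21, n_compounds=400, n_active=200,
                             n_latent_factors=10, family_counts={"other": 25}, noise_sd=0.2)
    train, _ = sd.gen_descriptor_matrix(cfg)
    red, result = reduce_matrix(train, k=10)
    model = grid_search_cv(
        ModelSpec(family="XGBoost", grid={"n_estimators": [100], "max_depth": [3]}),
        red, folds=5, seed=0,
    )
    lib_cfg = sd.GeneratorConfig(seed=22, n_compounds=400, n_active=200,
                                 n_latent_factors=10, family_counts={"other": 25}, noise_sd=0.2)
    lib, _ = sd.gen_descriptor_matrix(lib_cfg)
    out = screen_library(model, lib.subset_columns(result.selected_features))
    frac = out["label"].mean()
    assert abs(frac - 0.5) < 0.12  # ~4-5 binomial sd at n=400 plus model bias
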