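"""Classifier cross-validation, balanced-ensemble importances, rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hmppi.association import (
    ModelConfig,
    balanced_importance_ensemble,
    crossval,
    mannwhitney_targets,
    precluster_features,
    select_disease_associated,
)


def _toy_profiles(seed=0, n=60, p=10, separable=True):
    rng = np.random.default_rng(seed)
    X = rng.lognormal(size=(n, p))
    labels = ["case"] * (n // 2) + ["control"] * (n // 2)
    if separable:
        X[: n // 2, 0] += 50.0  # overwhelming effect on feature 0
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), labels


def test_crossval_separable_cohort_high_f1():
    X, y = _toy_profiles(separable=True)
    rep = crossval(X, y, ModelConfig(seed=0, n_iterations=5))
    assert rep.mean_f1 >= 0.95
    assert all(0 <= v <= 1 for v in rep.f1 + rep.precision + rep.recall)


def test_crossval_permuted_labels_near_chance():
    X, y = _toy_profiles(seed=1, n=80, separable=False)
    rng = np.random.default_rng(1)
    y = list(rng.permutation(y))
    rep = crossval(X, y, ModelConfig(seed=1))
    assert 0.25 <= rep.mean_f1 <= 0.75  # binomial noise band at n=80


def test_crossval_deterministic_given_seed():
    X, y = _toy_profiles(seed=2)
    cfg = ModelConfig(seed=5)
    r1, r2 = crossval(X, y, cfg), crossval(X, y, cfg)
    assert r1.f1 == r2.f1 and r1.best_params == r2.best_params


def test_crossval_single_class_rejected():
    X, _ = _toy_profiles()
    with pytest.raises(ValueError):
        crossval(X, ["case"] * len(X), ModelConfig())


def test_ensemble_separating_feature_tops_importance():
    X, y = _toy_profiles(seed=3)
    X["constant"] = 1.0
    cfg = ModelConfig(seed=3, n_iterations=10)
    imp = balanced_importance_ensemble(X, y, cfg, params={"n_estimators": 50})
    assert imp.mean_importance.idxmax() == "f0"
    assert imp.mean_importance["constant"] == 0.0  # never splits
    # per-iteration normalized importances sum to 1
    assert np.allclose(imp.per_iteration.sum(axis=1), 1.0)


def test_ensemble_undersamples_majority_class():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.lognormal(size=(90, 5)), columns=list("abcde"))
    y = ["case"] * 30 + ["control"] * 60
    cfg = ModelConfig(seed=4, n_iterations=3)
    imp = balanced_importance_ensemble(X, y, cfg, params={"n_estimators": 20})
    assert imp.mean_importance.shape == (5,)
    assert (imp.mean_importance >= 0).all()


def test_ensemble_ranking_stable_under_column_permutation():
    X, y = _toy_profiles(seed=6)
    cfg = ModelConfig(seed=6, n_iterations=10)
    imp1 = balanced_importance_ensemble(X, y, cfg, params={"n_estimators": 50})
    perm = list(X.columns)[::-1]
    imp2 = balanced_importance_ensemble(X[perm], y, cfg, params={"n_estimators": 50})
    assert imp1.mean_importance.idxmax() == imp2.mean_importance.idxmax() == "f0"


def test_selection_takes_strict_top_decile():
    imp = pd.Series(np.arange(100, dtype=float), index=[f"t{i}" for i in range(100)])
    sel = select_disease_associated(imp, 0.90)
    assert len(sel) == 10 and all(imp[t] > np.percentile(imp, 90) for t in sel)
    assert select_disease_associated(pd.Series(np.zeros(10)), 0.90) == []


def test_refit_on_selected_features_keeps_performance():
    X, y = _toy_profiles(seed=7, n=80, p=30)
    cfg = ModelConfig(seed=7, n_iterations=10)
    imp = balanced_importance_ensemble(X, y, cfg, params={"n_estimators": 50})
    selected = imp.selected_targets()
    assert "f0" in selected
    full = crossval(X, y, cfg).mean_f1
    subset = crossval(X[selected], y, cfg).mean_f1
    assert subset >= full - 0.05


def test_precluster_collapses_collinear_block():
    rng = np.random.default_rng(8)
    base = rng.normal(size=100)
    df = pd.DataFrame(
        {
            "a": base,
            "b": base * 2.0,  # r = 1 with a
            "c": base + rng.normal(scale=1e-6, size=100),
            "noise1": rng.normal(size=100),
            "noise2": rng.normal(size=100),
            "zerovar": np.ones(100),
        }
    )
    clusters, reps = precluster_features(df)
    by_member = {frozenset(c) for c in clusters}
    assert frozenset({"a", "b", "c"}) in by_member
    assert frozenset({"zerovar"}) in by_member
    assert {"noise1", "noise2"} <= set(reps.columns)
    # representative of the collinear block is its highest-variance member
    assert "b" in reps.columns and "a" not in reps.columns


def _exact_two_sided_p(x, y):
    """Exhaustive enumeration of all label assignments of the pooled data."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2

    def u_stat(group1, group2):
        return sum(1 for a in group1 for b in group2 if a > b) + 0.5 * sum(
            1 for a in group1 for b in group2 if a == b
        )

    obs = abs(u_stat(x, y) - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(g1, g2) - mu) >= obs - 1e-12:
            count += 1
    return count / total


def test_mannwhitney_exact_example_and_ties():
    df = pd.DataFrame({"t": [1, 2, 3, 4, 5, 6]}, index=[f"s{i}" for i in range(6)])
    labels = ["case"] * 3 + ["control"] * 3
    res = mannwhitney_targets(df, labels)
    assert res.loc["t", "U"] == 0.0
    assert res.loc["t", "p"] == pytest.approx(0.1)
    # identical values in both groups
    const = pd.DataFrame({"t": [5.0] * 6}, index=df.index)
    assert mannwhitney_targets(const, labels).loc["t", "p"] == 1.0


def test_mannwhitney_matches_enumeration_small_groups():
    rng = np.random.default_rng(9)
    for n1, n2 in [(3, 4), (5, 5), (6, 6)]:
        x = list(rng.normal(size=n1))
        y = list(rng.normal(size=n2))
        df = pd.DataFrame({"t": x + y}, index=[f"s{i}" for i in range(n1 + n2)])
        labels = ["case"] * n1 + ["control"] * n2
        got = mannwhitney_targets(df, labels).loc["t", "p"]
        assert got == pytest.approx(_exact_two_sided_p(x, y), abs=1e-9)


def test_mannwhitney_approximation_close_to_exact_at_n8():
    rng = np.random.default_rng(10)
    x, y = list(rng.normal(size=8)), list(rng.normal(size=8))
    exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    df = pd.DataFrame({"t": x + y}, index=[f"s{i}" for i in range(16)])
    got = mannwhitney_targets(df, ["case"] * 8 + ["control"] * 8).loc["t", "p"]
    assert got == pytest.approx(exact, abs=0.01)
    assert abs(approx - exact) < 0.01


def test_mannwhitney_empty_group_rejected():
    df = pd.DataFrame({"t": [1.0, 2.0]}, index=["s0", "s1"])
    with pytest.raises(ValueError):
        mannwhitney_targets(df, ["case", "case"])
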