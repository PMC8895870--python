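"""Case/control classification and disease-associated target selection.

The prioritization recipe: verify that a random forest separates cases
from controls under stratified five-fold cross-validation with a grid
search over hyperparameters, then train 100 class-balanced forests (the
majority class randomly undersampled to the minority size, fresh seed per
iteration), average the normalized Gini importances, and call targets
whose mean importance lies strictly above the 90th percentile
"disease-associated".  Per-target Mann-Whitney rank-sum tests provide the
univariate companion statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_validate
from sklearn.svm import SVC

from .config import DEFAULT_MODEL_GRID

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "CVReport",
    "ImportanceResult",
    "crossval",
    "balanced_importance_ensemble",
    "select_disease_associated",
    "precluster_features",
    "mannwhitney_targets",
]


@dataclass
class ModelConfig:
    n_folds: int = 5
    n_iterations: int = 100
    percentile: float = 0.90
    hyperparameter_grid: Mapping[str, list] = field(
        default_factory=lambda: dict(DEFAULT_MODEL_GRID)
    )
    seed: int = 0
    model_family: str = "random_forest"  # "random_forest" | "logistic" | "svm"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must lie in (0, 1)")


@dataclass
class CVReport:
    f1: list[float]
    precision: list[float]
    recall: list[float]
    best_params: dict

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))


@dataclass
class ImportanceResult:
    """Mean Gini importances over the balanced ensemble."""

    mean_importance: pd.Series  # indexed by target
    per_iteration: pd.DataFrame  # iterations x targets
    percentile_rank: pd.Series
    selected: pd.Series  # boolean

    def selected_targets(self) -> list[str]:
        return sorted(self.mean_importance.index[self.selected])


def _encode_labels(labels: Sequence[str] | pd.Series) -> np.ndarray:
    """case -> 1, control -> 0."""
    arr = np.asarray(labels)
    classes = np.unique(arr)
    if len(classes) < 2:
        raise ValueError("labels must contain two classes")
    return (arr == "case").astype(int) if "case" in classes else (arr == classes[1]).astype(int)


def _make_model(family: str, seed: int, **params):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "svm":
        return SVC(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}")


def crossval(
    profiles: pd.DataFrame, labels: Sequence[str], config: ModelConfig
) -> CVReport:
    """Stratified k-fold CV with grid-searched hyperparameters.

    The grid search (inner stratified CV on F1 of the case class) selects
    one hyperparameter setting; the report carries that setting's
    per-fold F1/precision/recall from an outer stratified k-fold.
    Deterministic given ``config.seed``.
    """
    y = _encode_labels(labels)
    X = profiles.to_numpy(dtype=float)
    cv = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    base = _make_model(config.model_family, config.seed)
    grid = (
        dict(config.hyperparameter_grid)
        if config.model_family == "random_forest"
        else {"C": [0.1, 1.0, 10.0]}
    )
    search = GridSearchCV(base, grid, scoring="f1", cv=cv, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
        best = search.best_params_
        scores = cross_validate(
            _make_model(config.model_family, config.seed, **best),
            X,
            y,
            cv=cv,
            scoring={"f1": "f1", "precision": "precision", "recall": "recall"},
            n_jobs=1,
        )
    return CVReport(
        f1=list(scores["test_f1"]),
        precision=list(scores["test_precision"]),
        recall=list(scores["test_recall"]),
        best_params=best,
    )


def _undersample_majority(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subsample (majority drawn down)."""
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    if len(idx0) > len(idx1):
        idx0 = rng.choice(idx0, size=len(idx1), replace=False)
    elif len(idx1) > len(idx0):
        idx1 = rng.choice(idx1, size=len(idx0), replace=False)
    return np.sort(np.concatenate([idx0, idx1]))


def balanced_importance_ensemble(
    profiles: pd.DataFrame,
    labels: Sequence[str],
    config: ModelConfig,
    params: Mapping | None = None,
) -> ImportanceResult:
    """Mean Gini importance from iteratively trained class-balanced forests.

    Each of ``config.n_iterations`` iterations undersamples the majority
    class to the minority size with seed ``config.seed + iteration`` and
    fits a random forest; per-forest importances (scikit-learn's
    normalized mean-decrease-in-impurity, summing to 1) are averaged.
    """
    y = _encode_labels(labels)
    X = profiles.to_numpy(dtype=float)
    minority = min(np.bincount(y))
    if minority < 5:
        warnings.warn("minority class has fewer than 5 samples; importances will be noisy")
    params = dict(params or {})
    per_iter = np.zeros((config.n_iterations, X.shape[1]))
    for it in range(config.n_iterations):
        seed = config.seed + it
        rng = np.random.default_rng(seed)
        idx = _undersample_majority(y, rng)
        model = RandomForestClassifier(random_state=seed, **params)
        model.fit(X[idx], y[idx])
        per_iter[it] = model.feature_importances_
    mean_imp = pd.Series(per_iter.mean(axis=0), index=profiles.columns)
    ranks = mean_imp.rank(pct=True)
    cutoff = float(np.percentile(mean_imp.to_numpy(), config.percentile * 100))
    selected = mean_imp > cutoff
    if not selected.any():
        warnings.warn("no target lies strictly above the importance percentile")
    return ImportanceResult(
        mean_importance=mean_imp,
        per_iteration=pd.DataFrame(per_iter, columns=profiles.columns),
        percentile_rank=ranks,
        selected=selected,
    )


def select_disease_associated(
    importances: ImportanceResult | pd.Series, percentile: float = 0.90
) -> list[str]:
    """Targets strictly above the linear-interpolated importance percentile."""
    mean_imp = (
        importances.mean_importance
        if isinstance(importances, ImportanceResult)
        else importances
    )
    cutoff = float(np.percentile(mean_imp.to_numpy(), percentile * 100))
    return sorted(mean_imp.index[mean_imp > cutoff])


def precluster_features(
    profiles: pd.DataFrame, r_threshold: float = 0.8
) -> tuple[list[list[str]], pd.DataFrame]:
    """Collapse collinear features before fitting correlation-sensitive models.

    Single-linkage components over the graph with an edge wherever
    Pearson r > ``r_threshold``; the representative of each component is
    its highest-variance member (ties break lexicographically).
    Zero-variance features become singleton clusters and contribute no
    correlation edges.  Returns (clusters, representative matrix).
    """
    if profiles.shape[1] < 2:
        raise ValueError("preclustering needs at least two features")
    cols = list(profiles.columns)
    X = profiles.to_numpy(dtype=float)
    var = X.var(axis=0)
    nz = var > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X[:, nz], rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr))

    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix(corr > r_threshold)
    n_comp, comp = connected_components(adj, directed=False)

    nz_cols = [c for c, keep in zip(cols, nz) if keep]
    clusters_map: dict[int, list[str]] = {}
    for col, lab in zip(nz_cols, comp):
        clusters_map.setdefault(lab, []).append(col)
    clusters = [sorted(v) for _, v in sorted(clusters_map.items())]
    clusters += [[c] for c, keep in zip(cols, nz) if not keep]

    var_s = pd.Series(var, index=cols)
    reps = [sorted(cl, key=lambda c: (-var_s[c], c))[0] for cl in clusters]
    reps = [r for r in profiles.columns if r in set(reps)]  # original order
    return clusters, profiles[reps]


def mannwhitney_targets(
    profiles: pd.DataFrame,
    labels: Sequence[str],
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney rank-sum test per target, cases vs controls.

    Uses the exact null distribution when both groups have at most 8
    samples and the data are tie-free, and the tie-corrected normal
    approximation otherwise.  Degenerate columns (all values identical)
    report p = 1.
    """
    y = _encode_labels(labels)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both case and control groups must be non-empty")
    targets = list(targets) if targets is not None else list(profiles.columns)
    rows = []
    for t in targets:
        x_case = profiles.loc[:, t].to_numpy(dtype=float)[y == 1]
        x_ctrl = profiles.loc[:, t].to_numpy(dtype=float)[y == 0]
        pooled = np.concatenate([x_case, x_ctrl])
        if np.ptp(pooled) == 0:
            rows.append({"target": t, "U": len(x_case) * len(x_ctrl) / 2, "p": 1.0})
            continue
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(x_case) <= 8 and len(x_ctrl) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x_case, x_ctrl, alternative="two-sided", method=method)
        rows.append({"target": t, "U": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("target")
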