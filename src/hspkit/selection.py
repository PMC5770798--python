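"""Feature ranking and top-k selection.

Five ranking techniques for a binary problem: the two-class F-score,
information gain (mutual information after equal-frequency discretization),
LASSO (absolute coefficients of an L1-penalized logistic fit with the
penalty chosen by internal cross-validation), random-forest impurity
importance, and squared weights of a linear large-margin classifier.
The default subset size is k = 484.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import mutual_info_score
from sklearn.svm import LinearSVC

TECHNIQUES = ("f_measure", "info_gain", "lasso", "random_forest", "svm_weight")

DEFAULT_K = 484


@dataclass
class RankedFeatures:
    """Features ordered by decreasing importance under one technique."""

    technique: str
    names: list[str]
    scores: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != self.scores.shape[0]:
            raise ValueError("names and scores length mismatch")
        with np.errstate(invalid="ignore"):  # inf - inf at tied infinities
            if np.any(np.diff(self.scores) > 0):
                raise ValueError("scores must be non-increasing")


@dataclass(frozen=True)
class SelectionResult:
    """The top-k feature names of one ranking."""

    technique: str
    selected: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.selected)


def _coerce(X, y):
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(values.shape[1])]
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.shape[0] != 2:
        raise ValueError(f"binary labels required, got classes {classes.tolist()}")
    if np.unique(y, return_counts=True)[1].min() < 2:
        raise ValueError("each class needs at least 2 examples")
    return values, names, y, classes


def _f_scores(values: np.ndarray, y, classes) -> np.ndarray:
    """Two-class F-score: between-class separation of the class means over
    pooled within-class scatter; 0/0 is scored 0."""
    pos, neg = values[y == classes[1]], values[y == classes[0]]
    mu, mu_p, mu_n = values.mean(0), pos.mean(0), neg.mean(0)
    num = (mu_p - mu) ** 2 + (mu_n - mu) ** 2
    den = pos.var(0, ddof=1) + neg.var(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                          np.where(num > 0, np.inf, 0.0))
    return scores


def _info_gain(values: np.ndarray, y, n_bins: int) -> np.ndarray:
    scores = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        # equal-frequency bins; constant columns collapse to one bin -> MI 0
        codes = pd.qcut(col, q=n_bins, labels=False, duplicates="drop")
        codes = np.nan_to_num(codes, nan=0.0).astype(int)
        scores[j] = mutual_info_score(y, codes)
    return scores


def rank_features(X, y, technique: str, seed: int = 0, **params) -> RankedFeatures:
    """Rank features of a binary problem by one of the five techniques.

    Stochastic techniques are reproducible given ``seed``; ties are broken
    by feature name order. Parameter overrides (``n_bins``, ``n_estimators``,
    ``Cs``, ``cv``, ``C``) are recorded in the result metadata.
    """
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")
    values, names, y, classes = _coerce(X, y)
    meta: dict = {}

    if technique == "f_measure":
        scores = _f_scores(values, y, classes)
    elif technique == "info_gain":
        n_bins = int(params.pop("n_bins", 10))
        meta["n_bins"] = n_bins
        scores = _info_gain(values, y, n_bins)
    elif technique == "lasso":
        if np.all(values.std(0) == 0):
            raise ValueError("degenerate fit: feature matrix is constant")
        Cs = params.pop("Cs", 10)
        cv = int(params.pop("cv", 3))
        meta.update(Cs=Cs, cv=cv, solver="liblinear", penalty="l1")
        model = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
            random_state=seed, max_iter=2000,
        ).fit(values, y)
        scores = np.abs(model.coef_.ravel())
    elif technique == "random_forest":
        n_estimators = int(params.pop("n_estimators", 500))
        meta["n_estimators"] = n_estimators
        model = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed
        ).fit(values, y)
        scores = model.feature_importances_
    else:  # svm_weight
        if np.all(values.std(0) == 0):
            raise ValueError("degenerate fit: feature matrix is constant")
        C = float(params.pop("C", 1.0))
        meta["C"] = C
        model = LinearSVC(C=C, random_state=seed, max_iter=20000).fit(values, y)
        scores = model.coef_.ravel() ** 2
    if params:
        raise ValueError(f"unknown parameter(s) for {technique!r}: {sorted(params)}")

    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return RankedFeatures(
        technique=technique,
        names=[names[i] for i in order],
        scores=scores[order],
        seed=seed,
        params=meta,
    )


def select_top_k(ranked: RankedFeatures, k: int = DEFAULT_K) -> SelectionResult:
    """The first k names of a ranking."""
    if not 1 <= k <= len(ranked.names):
        raise ValueError(
            f"k={k} out of range for {len(ranked.names)} ranked features"
        )
    return SelectionResult(technique=ranked.technique, selected=tuple(ranked.names[:k]))


def selection_overlap(results: list[SelectionResult]) -> dict:
    """Intersection cardinalities for every non-empty subset of techniques
    (the numbers behind a Venn diagram).

    Returns a dict with keys ``by_subset`` (frozenset of technique names ->
    size of the intersection of those selections), ``pairwise`` and
    ``global``.
    """
    if len(results) < 2:
        raise ValueError("need at least two selections to intersect")
    sets = {r.technique: set(r.selected) for r in results}
    if len(sets) != len(results):
        raise ValueError("duplicate technique names among selections")
    universe = set().union(*sets.values())
    for r in results:
        if not set(r.selected) <= universe:
            raise ValueError("mismatched feature universes")
    by_subset = {}
    techs = sorted(sets)
    for r in range(1, len(techs) + 1):
        for combo in combinations(techs, r):
            inter = set.intersection(*(sets[t] for t in combo))
            by_subset[frozenset(combo)] = len(inter)
    pairwise = {
        tuple(sorted(c)): by_subset[frozenset(c)] for c in combinations(techs, 2)
    }
    return {
        "by_subset": by_subset,
        "pairwise": pairwise,
        "global": by_subset[frozenset(techs)],
    }
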