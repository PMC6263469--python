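"""Feature selection and classifier tuning under leave-one-subject-out CV.

The selection pipeline:

1. drop one of every pair of highly correlated features (|Pearson r| >=
   0.9, absolute value — an anti-correlated copy is just as redundant),
2. rank the survivors by gain importance from a gradient-boosted-tree
   model,
3. recursive feature addition (RFA): walk the ranking, keep a feature only
   if it raises the mean leave-one-subject-out (LOSO) macro F1 by at least
   0.01 over the currently kept set,
4. tune the classifier on the selected features: the library defaults plus
   a seeded random sample from the family's parameter grid, scored by the
   same LOSO F1 (the defaults are always candidates, so tuning can never
   fall below them),
5. when several classifier families tie on F1 (within 0.005), prefer the
   one with the smallest measured fit+predict wall time.

LOSO treats each subject as one held-out fold; feature scaling to [0, 1]
is refitted inside every fold on the training subjects only, so no
statistic of a held-out subject leaks into training.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .errors import ParameterError
from .features import scale_features
from .io import feature_columns

FAMILIES = ("logreg", "knn", "dtree", "svm", "gbtree")

_TENTH_STEPS = [round(0.1 * i, 1) for i in range(1, 51)]  # 0.1 .. 5.0

#: Tuning grids, one axis per tunable parameter.
GRIDS: dict[str, dict[str, list]] = {
    "logreg": {"penalty": ["l1", "l2"], "C": list(_TENTH_STEPS)},
    "knn": {
        "n_neighbors": list(range(1, 11)),
        "weights": ["uniform", "distance"],
        "p": [1, 2],
        "algorithm": ["auto", "ball_tree", "kd_tree", "brute"],
    },
    "dtree": {
        "criterion": ["gini", "entropy"],
        "max_depth": list(range(1, 33)),
        "min_samples_split": [round(0.1 * i, 1) for i in range(1, 11)],
        "min_samples_leaf": [round(0.1 * i, 1) for i in range(1, 6)],
    },
    "svm": {
        "C": list(_TENTH_STEPS),
        "gamma": list(_TENTH_STEPS),
        "kernel": ["linear", "poly", "rbf", "sigmoid"],
    },
    "gbtree": {
        "learning_rate": [round(0.1 * i, 1) for i in range(1, 11)],
        "max_depth": list(range(3, 11)),
        "subsample": [round(0.1 * i, 1) for i in range(5, 11)],
    },
}

#: Library-default parameters per family (always part of the tuning
#: candidates, and expressible even where they fall outside the grid,
#: e.g. an unbounded tree depth).
DEFAULT_PARAMS: dict[str, dict] = {
    "logreg": {"penalty": "l2", "C": 1.0},
    "knn": {"n_neighbors": 5, "weights": "uniform", "p": 2, "algorithm": "auto"},
    "dtree": {
        "criterion": "gini",
        "max_depth": None,
        "min_samples_split": 2,
        "min_samples_leaf": 1,
    },
    "svm": {"C": 1.0, "gamma": "scale", "kernel": "rbf"},
    "gbtree": {"learning_rate": 0.1, "max_depth": 6, "subsample": 1.0},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus a concrete parameter assignment."""

    family: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown classifier family {self.family!r}")

    @classmethod
    def default(cls, family: str) -> "ClassifierSpec":
        return cls(family, dict(DEFAULT_PARAMS[family]))


def build_estimator(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the scikit-learn / xgboost estimator for a spec."""
    params = dict(spec.params)
    if spec.family == "logreg":
        # grid speaks in 'penalty' (l1/l2); newer scikit-learn wants l1_ratio
        penalty = params.pop("penalty", "l2")
        params["l1_ratio"] = 1.0 if penalty == "l1" else 0.0
        # one-vs-rest with liblinear, the classic multiclass scheme
        return OneVsRestClassifier(
            LogisticRegression(solver="liblinear", max_iter=1000, **params)
        )
    if spec.family == "knn":
        return KNeighborsClassifier(**params)
    if spec.family == "dtree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if spec.family == "svm":
        return SVC(random_state=seed, **params)
    if spec.family == "gbtree":
        return XGBClassifier(
            n_estimators=60,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
            **params,
        )
    raise ParameterError(f"unknown classifier family {spec.family!r}")


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit a fresh estimator and predict; gradient-boosted trees get their
    string labels integer-encoded transparently."""
    est = build_estimator(spec, seed)
    if spec.family == "gbtree":
        enc = LabelEncoder().fit(y_train)
        est.fit(X_train, enc.transform(y_train))
        return enc.inverse_transform(est.predict(X_test))
    est.fit(X_train, y_train)
    return est.predict(X_test)


# ---------------------------------------------------------------------------
# Correlation pre-filter and importance ranking
# ---------------------------------------------------------------------------


def correlation_filter(
    table: pd.DataFrame,
    threshold: float = 0.9,
    order: Sequence[str] | None = None,
) -> list[str]:
    """Greedy de-duplication of features with |Pearson r| >= threshold.

    Features are scanned in ``order`` (default: table column order); a
    feature is dropped if it correlates at or above the threshold with any
    already retained feature, so the earlier member of a redundant pair
    survives.  Zero-variance features have no defined correlation; they
    are retained and flagged with a warning.
    """
    feats = list(order) if order is not None else feature_columns(table)
    if len(table) < 2:
        raise ParameterError("correlation filter requires at least 2 rows")
    values = table[feats].to_numpy(dtype=float)
    constant = values.std(axis=0) == 0
    if constant.any():
        flagged = [f for f, c in zip(feats, constant) if c]
        warnings.warn(f"zero-variance features retained: {flagged}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(values, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    retained_idx: list[int] = []
    for j in range(len(feats)):
        if all(corr[j, i] < threshold for i in retained_idx):
            retained_idx.append(j)
        elif constant[j]:
            retained_idx.append(j)
    return [feats[j] for j in retained_idx]


def rank_features(
    table: pd.DataFrame,
    labels: Sequence[str],
    features: Sequence[str] | None = None,
    seed: int = 0,
) -> list[str]:
    """Order features by gain importance of a boosted-tree fit, descending.

    Deterministic for a given seed; features the booster never split on
    get zero gain; ties break alphabetically.
    """
    feats = list(features) if features is not None else feature_columns(table)
    feats = sorted(feats)  # canonical order: ranking ignores column order
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ParameterError("ranking requires at least two classes")
    model = XGBClassifier(
        n_estimators=50,
        max_depth=6,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )
    y = LabelEncoder().fit_transform(labels)
    model.fit(table[feats].to_numpy(dtype=float), y)
    raw = model.get_booster().get_score(importance_type="gain")
    gains = {f: raw.get(f"f{i}", 0.0) for i, f in enumerate(feats)}
    return sorted(feats, key=lambda f: (-gains[f], f))


# ---------------------------------------------------------------------------
# LOSO evaluation
# ---------------------------------------------------------------------------


def loso_f1(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    labels: Sequence[str],
    subjects: Sequence[str],
    features: Sequence[str] | None = None,
    seed: int = 0,
) -> float:
    """Mean macro-F1 over leave-one-subject-out folds.

    Per fold: [0, 1] feature scaling is fitted on the training subjects,
    the classifier is fitted on the scaled training rows and scored on the
    held-out subject with macro-averaged F1; folds whose training set
    lacks a class are skipped with a warning.
    """
    scores = loso_f1_per_fold(spec, table, labels, subjects, features, seed)
    if not scores:
        raise ParameterError("no evaluable LOSO folds")
    return float(np.mean(list(scores.values())))


def loso_f1_per_fold(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    labels: Sequence[str],
    subjects: Sequence[str],
    features: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, float]:
    feats = list(features) if features is not None else feature_columns(table)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    if len(np.unique(subjects)) < 2:
        raise ParameterError("LOSO requires at least two subjects")
    classes = np.unique(labels)
    sub_table = table[feats].reset_index(drop=True)
    scores: dict[str, float] = {}
    for subject in sorted(np.unique(subjects)):
        test_mask = subjects == subject
        y_train = labels[~test_mask]
        if len(np.unique(y_train)) < len(classes):
            warnings.warn(
                f"fold {subject!r} skipped: class missing from training set",
                stacklevel=2,
            )
            continue
        train_df = sub_table[~test_mask]
        test_df = sub_table[test_mask]
        train_scaled, test_scaled = scale_features(train_df, test_df)
        pred = fit_predict(
            spec,
            train_scaled.to_numpy(dtype=float),
            y_train,
            test_scaled.to_numpy(dtype=float),
            seed=seed,
        )
        scores[str(subject)] = float(
            f1_score(labels[test_mask], pred, average="macro", zero_division=0)
        )
    return scores


# ---------------------------------------------------------------------------
# Recursive feature addition
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Outcome of correlation filtering + ranking + recursive addition."""

    ranking: list[str]
    retained: list[str]
    selected: list[str]
    trace: list[tuple[str, float, bool]]  # (candidate, F1 with it added, kept?)
    final_f1: float


def rfa_select(
    table: pd.DataFrame,
    labels: Sequence[str],
    subjects: Sequence[str],
    spec: ClassifierSpec,
    delta: float = 0.01,
    corr_threshold: float = 0.9,
    max_candidates: int | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Forward selection in importance order under the LOSO F1 criterion.

    Starts from the top-ranked feature; each following candidate is kept
    only if adding it raises the kept-set mean LOSO F1 by at least
    ``delta``.  The kept-set F1 is therefore non-decreasing along the
    trace.  ``max_candidates`` truncates the ranking for budgeted runs.
    """
    retained = correlation_filter(table, corr_threshold)
    ranking = rank_features(table, labels, retained, seed=seed)
    candidates = ranking[:max_candidates] if max_candidates else ranking

    selected = [candidates[0]]
    current = loso_f1(spec, table, labels, subjects, selected, seed=seed)
    trace: list[tuple[str, float, bool]] = [(candidates[0], current, True)]
    for cand in candidates[1:]:
        trial = loso_f1(spec, table, labels, subjects, selected + [cand], seed=seed)
        keep = trial - current >= delta
        if keep:
            selected.append(cand)
            current = trial
        trace.append((cand, trial, keep))
    return SelectionResult(
        ranking=list(ranking),
        retained=retained,
        selected=selected,
        trace=trace,
        final_f1=current,
    )


# ---------------------------------------------------------------------------
# Tuning and per-node model selection
# ---------------------------------------------------------------------------


def sample_grid(family: str, rng: np.random.Generator) -> dict:
    """One uniform random draw from a family's parameter grid."""
    grid = GRIDS[family]
    return {name: options[rng.integers(len(options))] for name, options in grid.items()}


def tune_classifier(
    family: str,
    table: pd.DataFrame,
    labels: Sequence[str],
    subjects: Sequence[str],
    features: Sequence[str] | None = None,
    budget: int = 10,
    seed: int = 0,
) -> tuple[ClassifierSpec, float]:
    """Default parameters plus ``budget`` seeded random grid draws, scored
    by LOSO F1; returns the best (first encountered wins ties), which by
    construction is never worse than the defaults."""
    if family not in FAMILIES:
        raise ParameterError(f"unknown classifier family {family!r}")
    if budget < 0:
        raise ParameterError("budget must be >= 0")
    rng = np.random.default_rng(seed)
    candidates = [ClassifierSpec.default(family)]
    for _ in range(budget):
        candidates.append(ClassifierSpec(family, sample_grid(family, rng)))
    best_spec, best_f1 = candidates[0], -1.0
    for spec in candidates:
        score = loso_f1(spec, table, labels, subjects, features, seed=seed)
        if score > best_f1:
            best_spec, best_f1 = spec, score
    return best_spec, best_f1


@dataclass
class NodeCandidate:
    """One classifier family's full selection + tuning outcome."""

    spec: ClassifierSpec
    features: list[str]
    f1: float
    fit_predict_seconds: float
    selection: SelectionResult


@dataclass
class NodeSelection:
    """Chosen model for one node task, plus the per-family comparison."""

    spec: ClassifierSpec
    features: list[str]
    f1: float
    fit_predict_seconds: float
    candidates: dict[str, NodeCandidate]

    def report(self) -> pd.DataFrame:
        rows = [
            {
                "family": fam,
                "f1": c.f1,
                "n_features": len(c.features),
                "fit_predict_seconds": c.fit_predict_seconds,
                "chosen": c.spec == self.spec and c.features == self.features,
            }
            for fam, c in self.candidates.items()
        ]
        return pd.DataFrame(rows)


def _time_fit_predict(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    labels: Sequence[str],
    features: Sequence[str],
    seed: int,
) -> float:
    X = table[list(features)].to_numpy(dtype=float)
    y = np.asarray(labels)
    start = time.perf_counter()
    fit_predict(spec, X, y, X, seed=seed)
    return time.perf_counter() - start


def select_node_model(
    table: pd.DataFrame,
    labels: Sequence[str],
    subjects: Sequence[str],
    families: Sequence[str] = FAMILIES,
    budget: int = 10,
    delta: float = 0.01,
    max_candidates: int | None = None,
    f1_tie_tolerance: float = 0.005,
    seed: int = 0,
) -> NodeSelection:
    """Run RFA + tuning per family and pick the winner.

    Highest LOSO F1 wins; families within ``f1_tie_tolerance`` of the best
    are treated as tied and the one with the smallest measured fit+predict
    wall time is preferred — equal scores should not cost extra compute.
    """
    if not families:
        raise ParameterError("at least one classifier family is required")
    candidates: dict[str, NodeCandidate] = {}
    for family in families:
        sel = rfa_select(
            table,
            labels,
            subjects,
            ClassifierSpec.default(family),
            delta=delta,
            max_candidates=max_candidates,
            seed=seed,
        )
        spec, f1 = tune_classifier(
            family, table, labels, subjects, sel.selected, budget=budget, seed=seed
        )
        elapsed = _time_fit_predict(spec, table, labels, sel.selected, seed)
        candidates[family] = NodeCandidate(spec, sel.selected, f1, elapsed, sel)

    best_f1 = max(c.f1 for c in candidates.values())
    tied = [c for c in candidates.values() if c.f1 >= best_f1 - f1_tie_tolerance]
    winner = min(tied, key=lambda c: c.fit_predict_seconds)
    return NodeSelection(
        spec=winner.spec,
        features=winner.features,
        f1=winner.f1,
        fit_predict_seconds=winner.fit_predict_seconds,
        candidates=candidates,
    )
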