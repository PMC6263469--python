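"""Seven node tasks and the two top-down hierarchical compositions.

The six target positions factor into side (right/left) and segment
(arm/hand/thigh), giving seven local classification problems:

====================  ========================================  ========
node                  rows                                      classes
====================  ========================================  ========
body_side             all positions                             2
body_segment          all positions                             3
left_segment          left_* positions                          3
right_segment         right_* positions                         3
arm_side              right_arm / left_arm                      2
hand_side             right_hand / left_hand                    2
thigh_side            right_thigh / left_thigh                  2
====================  ========================================  ========

Two local-classifier-per-parent-node compositions solve the 6-class
problem top-down: the *segment* approach classifies the segment first and
routes each window to that segment's side node; the *side* approach
classifies the side first and routes to that side's segment node.  A
window is labeled correctly only if both stages are correct, so end-to-end
accuracy can never exceed root accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.preprocessing import LabelEncoder

from .errors import ParameterError, ValidationError
from .features import scale_features
from .io import POSITIONS, position_segment, position_side
from .selection import (
    ClassifierSpec,
    NodeSelection,
    build_estimator,
    select_node_model,
)

SIDES = ("right", "left")
SEGMENTS = ("arm", "hand", "thigh")

APPROACHES = ("segment_top_down", "side_top_down")


@dataclass(frozen=True)
class NodeTask:
    """One local classification problem: eligible rows and label mapping."""

    id: str
    eligible_positions: tuple[str, ...]
    label_map: Mapping[str, str]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.label_map.values())))


def _side_task(segment: str | None) -> dict[str, str]:
    eligible = [p for p in POSITIONS if segment is None or position_segment(p) == segment]
    return {p: position_side(p) for p in eligible}


def _segment_task(side: str | None) -> dict[str, str]:
    eligible = [p for p in POSITIONS if side is None or position_side(p) == side]
    return {p: position_segment(p) for p in eligible}


NODE_TASKS: dict[str, NodeTask] = {
    "body_side": NodeTask("body_side", POSITIONS, _side_task(None)),
    "body_segment": NodeTask("body_segment", POSITIONS, _segment_task(None)),
    "left_segment": NodeTask(
        "left_segment", tuple(_segment_task("left")), _segment_task("left")
    ),
    "right_segment": NodeTask(
        "right_segment", tuple(_segment_task("right")), _segment_task("right")
    ),
    "arm_side": NodeTask("arm_side", tuple(_side_task("arm")), _side_task("arm")),
    "hand_side": NodeTask("hand_side", tuple(_side_task("hand")), _side_task("hand")),
    "thigh_side": NodeTask(
        "thigh_side", tuple(_side_task("thigh")), _side_task("thigh")
    ),
}

#: root node and child nodes (keyed by root output) per approach
APPROACH_LAYOUT: dict[str, tuple[str, dict[str, str]]] = {
    "segment_top_down": (
        "body_segment",
        {"arm": "arm_side", "hand": "hand_side", "thigh": "thigh_side"},
    ),
    "side_top_down": (
        "body_side",
        {"right": "right_segment", "left": "left_segment"},
    ),
}


def build_node_dataset(
    table: pd.DataFrame, task: NodeTask
) -> tuple[pd.DataFrame, np.ndarray]:
    """Restrict a 6-class feature table to a node's rows and relabel them."""
    mask = table["position"].isin(task.eligible_positions)
    rows = table[mask].reset_index(drop=True)
    labels = rows["position"].map(dict(task.label_map)).to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValidationError(f"node {task.id!r} has fewer than 2 classes present")
    return rows, labels


@dataclass
class NodeModel:
    """A trained local classifier: spec, feature subset and scaler stats."""

    task_id: str
    spec: ClassifierSpec
    features: list[str]
    estimator: object
    label_encoder: object  # None unless the estimator needs integer labels
    train_min: pd.Series
    train_max: pd.Series
    cv_f1: float
    seed: int = 0

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in rows.columns]
        if missing:
            raise ParameterError(f"rows missing feature columns {missing}")
        span = (self.train_max - self.train_min).replace(0.0, np.nan)
        scaled = ((rows[self.features] - self.train_min) / span).clip(0.0, 1.0)
        scaled = scaled.fillna(0.0)
        pred = self.estimator.predict(scaled.to_numpy(dtype=float))
        if self.label_encoder is not None:
            pred = self.label_encoder.inverse_transform(pred)
        return np.asarray(pred)


@dataclass
class HierarchyModel:
    """Root + child node models under one top-down approach."""

    approach: str
    root: NodeModel
    children: dict[str, NodeModel]

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ParameterError(f"unknown approach {self.approach!r}")
        expected = set(APPROACH_LAYOUT[self.approach][1])
        if set(self.children) != expected:
            raise ValidationError(f"children must be keyed by {sorted(expected)}")


@dataclass
class SelectionSettings:
    """Budget knobs threaded into per-node selection and tuning."""

    families: tuple[str, ...] = ("logreg", "knn", "dtree", "svm", "gbtree")
    budget: int = 10
    delta: float = 0.01
    max_candidates: int | None = None
    f1_tie_tolerance: float = 0.005
    seed: int = 0


def _fit_node(
    table: pd.DataFrame,
    labels: np.ndarray,
    task_id: str,
    spec: ClassifierSpec,
    features: Sequence[str],
    cv_f1: float,
    seed: int,
) -> NodeModel:
    feats = list(features)
    lo = table[feats].min(axis=0)
    hi = table[feats].max(axis=0)
    scaled, _ = scale_features(table[feats])
    labels = np.asarray(labels)
    estimator = build_estimator(spec, seed)
    encoder = None
    y = labels
    if spec.family == "gbtree":
        encoder = LabelEncoder().fit(labels)
        y = encoder.transform(labels)
    estimator.fit(scaled.to_numpy(dtype=float), y)
    return NodeModel(
        task_id=task_id,
        spec=spec,
        features=feats,
        estimator=estimator,
        label_encoder=encoder,
        train_min=lo,
        train_max=hi,
        cv_f1=cv_f1,
        seed=seed,
    )


def fit_node_model(
    table: pd.DataFrame,
    task_id: str,
    settings: SelectionSettings,
    selection: NodeSelection | None = None,
) -> NodeModel:
    """Select (unless a selection is supplied) and fit one node model."""
    task = NODE_TASKS[task_id]
    rows, labels = build_node_dataset(table, task)
    if selection is None:
        selection = select_node_model(
            rows,
            labels,
            rows["subject_id"].to_numpy(),
            families=settings.families,
            budget=settings.budget,
            delta=settings.delta,
            max_candidates=settings.max_candidates,
            f1_tie_tolerance=settings.f1_tie_tolerance,
            seed=settings.seed,
        )
    return _fit_node(
        rows, labels, task_id, selection.spec, selection.features, selection.f1,
        settings.seed,
    )


def fit_hierarchy(
    approach: str,
    table: pd.DataFrame,
    settings: SelectionSettings = SelectionSettings(),
    selections: Mapping[str, NodeSelection] | None = None,
) -> HierarchyModel:
    """Fit root and child node models for one approach on a feature table.

    ``selections`` may carry precomputed per-node feature/classifier
    choices (e.g. from a selection pass on the full table); otherwise
    selection runs on the supplied rows.
    """
    if approach not in APPROACHES:
        raise ParameterError(f"unknown approach {approach!r}")
    root_id, child_map = APPROACH_LAYOUT[approach]
    sel = selections or {}
    root = fit_node_model(table, root_id, settings, sel.get(root_id))
    children = {
        key: fit_node_model(table, node_id, settings, sel.get(node_id))
        for key, node_id in child_map.items()
    }
    return HierarchyModel(approach=approach, root=root, children=children)


def predict_position(model: HierarchyModel, rows: pd.DataFrame) -> np.ndarray:
    """Route each row through root and child models to a 6-class label."""
    root_pred = model.root.predict(rows)
    final = np.empty(len(rows), dtype=object)
    for key, child in model.children.items():
        mask = root_pred == key
        if not mask.any():
            continue
        child_pred = child.predict(rows[mask])
        if model.approach == "segment_top_down":
            combined = [f"{side}_{key}" for side in child_pred]
        else:
            combined = [f"{key}_{segment}" for segment in child_pred]
        final[mask] = combined
    return final.astype(str)


# ---------------------------------------------------------------------------
# LOSO evaluation of nodes and full hierarchies
# ---------------------------------------------------------------------------


def evaluate_node(
    task_id: str,
    table: pd.DataFrame,
    settings: SelectionSettings = SelectionSettings(),
    refit_per_fold: bool = True,
) -> dict:
    """Subject-held-out evaluation of a single node task.

    With ``refit_per_fold`` the feature/classifier selection reruns inside
    every fold (no selection leakage); without it, selection happens once
    on all rows and only the classifier is refitted per fold — faster but
    optimistic, since the held-out subject influenced the selection.
    """
    task = NODE_TASKS[task_id]
    rows, labels = build_node_dataset(table, task)
    subjects = rows["subject_id"].to_numpy()
    fixed = None
    if not refit_per_fold:
        fixed = select_node_model(
            rows, labels, subjects,
            families=settings.families, budget=settings.budget,
            delta=settings.delta, max_candidates=settings.max_candidates,
            f1_tie_tolerance=settings.f1_tie_tolerance, seed=settings.seed,
        )
    per_fold: dict[str, float] = {}
    for subject in sorted(np.unique(subjects)):
        test_mask = subjects == subject
        train = rows[~test_mask].reset_index(drop=True)
        test = rows[test_mask]
        if fixed is None:
            sel = select_node_model(
                train, labels[~test_mask], train["subject_id"].to_numpy(),
                families=settings.families, budget=settings.budget,
                delta=settings.delta, max_candidates=settings.max_candidates,
                f1_tie_tolerance=settings.f1_tie_tolerance, seed=settings.seed,
            )
        else:
            sel = fixed
        node = _fit_node(
            train, labels[~test_mask], task_id, sel.spec, sel.features, sel.f1,
            settings.seed,
        )
        pred = node.predict(test)
        per_fold[str(subject)] = float(
            f1_score(labels[test_mask], pred, average="macro", zero_division=0)
        )
    return {
        "task": task_id,
        "per_fold_f1": per_fold,
        "mean_f1": float(np.mean(list(per_fold.values()))),
    }


def evaluate_hierarchy(
    table: pd.DataFrame,
    settings: SelectionSettings = SelectionSettings(),
    approaches: Sequence[str] = APPROACHES,
    refit_per_fold: bool = True,
) -> dict:
    """Hierarchy-level LOSO: fit on all-but-one subject, score the held-out
    subject end to end; both approaches share identical fold splits.

    Per approach and fold the report carries end-to-end 6-class accuracy
    and macro precision/recall/F1, plus the root node's own accuracy (the
    composition bound: end-to-end accuracy <= root accuracy, since a
    misrouted window can never recover its true label).
    """
    subjects = np.unique(table["subject_id"].to_numpy())
    if len(subjects) < 2:
        raise ParameterError("hierarchy evaluation requires at least two subjects")

    selections: dict[str, Mapping[str, NodeSelection]] = {}
    if not refit_per_fold:
        needed = {
            node_id
            for approach in approaches
            for node_id in (
                [APPROACH_LAYOUT[approach][0]]
                + list(APPROACH_LAYOUT[approach][1].values())
            )
        }
        global_sel: dict[str, NodeSelection] = {}
        for node_id in sorted(needed):
            rows, labels = build_node_dataset(table, NODE_TASKS[node_id])
            global_sel[node_id] = select_node_model(
                rows, labels, rows["subject_id"].to_numpy(),
                families=settings.families, budget=settings.budget,
                delta=settings.delta, max_candidates=settings.max_candidates,
                f1_tie_tolerance=settings.f1_tie_tolerance, seed=settings.seed,
            )
        selections = {a: global_sel for a in approaches}

    report: dict = {"approaches": {}, "subjects": [str(s) for s in sorted(subjects)]}
    for approach in approaches:
        root_id, _ = APPROACH_LAYOUT[approach]
        folds = []
        for subject in sorted(subjects):
            test_mask = table["subject_id"].to_numpy() == subject
            train = table[~test_mask].reset_index(drop=True)
            test = table[test_mask].reset_index(drop=True)
            model = fit_hierarchy(
                approach, train, settings, selections.get(approach)
            )
            pred = predict_position(model, test)
            truth = test["position"].to_numpy()
            root_task = NODE_TASKS[root_id]
            root_truth = test["position"].map(dict(root_task.label_map)).to_numpy()
            root_pred = model.root.predict(test)
            folds.append(
                {
                    "subject": str(subject),
                    "accuracy": float(np.mean(pred == truth)),
                    "macro_f1": float(
                        f1_score(truth, pred, average="macro", zero_division=0)
                    ),
                    "root_accuracy": float(np.mean(root_pred == root_truth)),
                }
            )
        report["approaches"][approach] = {
            "per_fold": folds,
            "mean_accuracy": float(np.mean([f["accuracy"] for f in folds])),
            "mean_macro_f1": float(np.mean([f["macro_f1"] for f in folds])),
            "mean_root_accuracy": float(np.mean([f["root_accuracy"] for f in folds])),
        }
    return report


def confusion_matrix_text(truth: Sequence[str], pred: Sequence[str]) -> str:
    """Plain-text confusion matrix over the 6 positions."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    labels = list(POSITIONS)
    width = max(len(l) for l in labels) + 2
    lines = [" " * width + "".join(f"{l:>{width}}" for l in labels)]
    for t in labels:
        row = [f"{t:>{width}}"]
        for p in labels:
            row.append(f"{int(np.sum((truth == t) & (pred == p))):>{width}}")
        lines.append("".join(row))
    return "\n".join(lines)
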