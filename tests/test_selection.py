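import numpy as np
import pandas as pd
import pytest

from imupos.errors import ParameterError
from imupos.selection import (
    ClassifierSpec,
    DEFAULT_PARAMS,
    FAMILIES,
    GRIDS,
    correlation_filter,
    loso_f1,
    loso_f1_per_fold,
    rank_features,
    rfa_select,
    sample_grid,
    select_node_model,
    tune_classifier,
)


def make_table(features: dict, subjects=None):
    t = pd.DataFrame(features)
    n = len(t)
    t["subject_id"] = subjects if subjects is not None else [f"P{i % 5}" for i in range(n)]
    t["position"] = "right_arm"
    t["sensor_kind"] = "accelerometer"
    t["window_index"] = range(n)
    return t


def planted_dataset(n_subjects=10, per_subject=30, n_noise=20, sep=3.0, seed=0):
    """Binary labels carried by one informative feature among pure noise."""
    rng = np.random.default_rng(seed)
    rows = n_subjects * per_subject
    labels = rng.integers(0, 2, rows)
    informative = labels * sep + rng.normal(size=rows)
    feats = {"informative": informative}
    feats.update({f"noise{i:02d}": rng.normal(size=rows) for i in range(n_noise)})
    subjects = np.repeat([f"P{i}" for i in range(n_subjects)], per_subject)
    return make_table(feats, subjects), np.where(labels == 1, "a", "b"), subjects


class TestCorrelationFilter:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=100)
        table = make_table({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        assert correlation_filter(table) == ["a", "c"]

    def test_negated_column_dropped(self, rng):
        x = rng.normal(size=100)
        table = make_table({"a": x, "neg": -x})
        assert correlation_filter(table) == ["a"]

    def test_independent_columns_all_retained(self, rng):
        table = make_table({f"f{i}": rng.normal(size=500) for i in range(8)})
        assert len(correlation_filter(table)) == 8

    def test_zero_variance_column_retained_with_warning(self, rng):
        table = make_table({"a": rng.normal(size=50), "flat": np.ones(50)})
        with pytest.warns(UserWarning, match="zero-variance"):
            retained = correlation_filter(table)
        assert "flat" in retained


class TestRankFeatures:
    def test_planted_feature_ranks_first(self):
        table, labels, _ = planted_dataset(seed=7)
        ranking = rank_features(table, labels, seed=0)
        assert ranking[0] == "informative"

    def test_column_order_invariance(self):
        table, labels, _ = planted_dataset(seed=3)
        feats = [c for c in table.columns if c not in ("subject_id", "position", "sensor_kind", "window_index")]
        shuffled = table[feats[::-1] + ["subject_id", "position", "sensor_kind", "window_index"]]
        assert rank_features(table, labels, feats, seed=0) == rank_features(
            shuffled, labels, feats[::-1], seed=0
        )

    def test_reproducible_per_seed_on_null_labels(self, rng):
        table = make_table({f"f{i}": rng.normal(size=120) for i in range(6)})
        labels = np.array(["a", "b"] * 60)
        assert rank_features(table, labels, seed=5) == rank_features(table, labels, seed=5)

    def test_single_class_rejected(self, rng):
        table = make_table({"f": rng.normal(size=20)})
        with pytest.raises(ParameterError):
            rank_features(table, np.repeat("a", 20))


class TestLosoF1:
    def test_separable_classes_score_one(self):
        table, labels, subjects = planted_dataset(sep=50.0, n_noise=1, seed=1)
        spec = ClassifierSpec.default("logreg")
        assert loso_f1(spec, table, labels, subjects, ["informative"]) == 1.0

    def test_fold_count_equals_subject_count(self):
        table, labels, subjects = planted_dataset(n_subjects=6, seed=2)
        scores = loso_f1_per_fold(
            ClassifierSpec.default("knn"), table, labels, subjects, ["informative"]
        )
        assert len(scores) == 6

    def test_null_labels_score_near_half(self, rng):
        # labels independent of the features: macro F1 should hover at chance
        scores = []
        for rep in range(10):
            r = np.random.default_rng(rep)
            table = make_table(
                {"f1": r.normal(size=200), "f2": r.normal(size=200)},
                subjects=np.repeat([f"P{i}" for i in range(10)], 20),
            )
            labels = np.where(r.integers(0, 2, 200) == 1, "a", "b")
            scores.append(
                loso_f1(
                    ClassifierSpec.default("logreg"),
                    table,
                    labels,
                    table["subject_id"].to_numpy(),
                    ["f1", "f2"],
                )
            )
        assert abs(np.mean(scores) - 0.5) < 0.1

    def test_missing_class_fold_skipped_with_warning(self):
        table = make_table(
            {"f": np.arange(40.0)}, subjects=np.repeat(["P0", "P1"], 20)
        )
        labels = np.array(["a"] * 20 + ["b"] * 10 + ["a"] * 10)
        with pytest.warns(UserWarning, match="skipped"):
            scores = loso_f1_per_fold(
                ClassifierSpec.default("dtree"), table, labels,
                table["subject_id"].to_numpy(), ["f"],
            )
        # holding out P1 leaves single-class training data, so only the
        # P0 fold is evaluable
        assert list(scores) == ["P0"]


class TestRfaSelect:
    def test_trace_covers_all_candidates_and_kept_f1_monotone(self):
        table, labels, subjects = planted_dataset(n_noise=6, seed=4)
        res = rfa_select(table, labels, subjects, ClassifierSpec.default("logreg"))
        assert len(res.trace) == len(res.ranking)
        kept = [f1 for _, f1, keep in res.trace if keep]
        assert all(b >= a for a, b in zip(kept, kept[1:]))
        assert res.final_f1 >= kept[0]
        assert set(res.selected) <= set(res.retained)

    def test_perfect_first_feature_blocks_additions(self):
        table, labels, subjects = planted_dataset(sep=50.0, n_noise=5, seed=5)
        res = rfa_select(table, labels, subjects, ClassifierSpec.default("logreg"))
        assert res.selected == ["informative"]
        assert res.final_f1 == 1.0

    def test_impossible_delta_keeps_exactly_one(self):
        table, labels, subjects = planted_dataset(n_noise=4, seed=6)
        res = rfa_select(
            table, labels, subjects, ClassifierSpec.default("knn"), delta=1.1
        )
        assert len(res.selected) == 1

    def test_complementary_features_both_kept(self):
        # XOR-style: each feature alone is uninformative, together perfect
        rng = np.random.default_rng(9)
        rows = 400
        a = rng.integers(0, 2, rows)
        b = rng.integers(0, 2, rows)
        labels = np.where(a ^ b == 1, "x", "y")
        table = make_table(
            {
                "bit_a": a + rng.normal(0, 0.05, rows),
                "bit_b": b + rng.normal(0, 0.05, rows),
                "noise": rng.normal(size=rows),
            },
            subjects=np.repeat([f"P{i}" for i in range(8)], 50),
        )
        res = rfa_select(
            table, labels, table["subject_id"].to_numpy(),
            ClassifierSpec.default("knn"),
        )
        assert {"bit_a", "bit_b"} <= set(res.selected)
        assert "noise" not in res.selected

    def test_null_data_selects_few_features(self):
        # guards against chasing F1 noise: on chance-level data the kept
        # set stays a small fraction of the 15 candidates (the chance of a
        # spurious +0.01 LOSO-F1 jump keeps the ratchet slow)
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            table = make_table(
                {f"f{i:02d}": rng.normal(size=200) for i in range(15)},
                subjects=np.repeat([f"P{i}" for i in range(10)], 20),
            )
            labels = np.where(rng.integers(0, 2, 200) == 1, "a", "b")
            res = rfa_select(
                table, labels, table["subject_id"].to_numpy(),
                ClassifierSpec.default("logreg"),
            )
            sizes.append(len(res.selected))
        assert np.mean(sizes) <= 5.0
        assert max(sizes) < 10


class TestTuneClassifier:
    def test_zero_budget_returns_defaults(self):
        table, labels, subjects = planted_dataset(n_noise=1, seed=8)
        spec, _ = tune_classifier(
            "knn", table, labels, subjects, ["informative"], budget=0
        )
        assert dict(spec.params) == DEFAULT_PARAMS["knn"]

    def test_tuned_never_below_default(self):
        table, labels, subjects = planted_dataset(n_noise=2, sep=1.0, seed=9)
        default_f1 = loso_f1(
            ClassifierSpec.default("dtree"), table, labels, subjects, ["informative"]
        )
        _, tuned_f1 = tune_classifier(
            "dtree", table, labels, subjects, ["informative"], budget=4, seed=3
        )
        assert tuned_f1 >= default_f1

    def test_deterministic_for_seed_and_budget(self):
        table, labels, subjects = planted_dataset(n_noise=2, sep=1.0, seed=10)
        a = tune_classifier("logreg", table, labels, subjects, ["informative"], budget=3, seed=7)
        b = tune_classifier("logreg", table, labels, subjects, ["informative"], budget=3, seed=7)
        assert a == b

    @pytest.mark.parametrize("family", FAMILIES)
    def test_grid_draws_stay_inside_grid(self, family):
        rng = np.random.default_rng(0)
        for _ in range(20):
            draw = sample_grid(family, rng)
            for name, value in draw.items():
                assert value in GRIDS[family][name]


class TestSelectNodeModel:
    def test_report_and_tie_break(self):
        table, labels, subjects = planted_dataset(sep=50.0, n_noise=3, seed=11)
        sel = select_node_model(
            table, labels, subjects,
            families=("logreg", "knn"), budget=0, max_candidates=4,
        )
        assert set(sel.candidates) == {"logreg", "knn"}
        best_f1 = max(c.f1 for c in sel.candidates.values())
        assert sel.f1 >= best_f1 - 0.005
        tied = [c for c in sel.candidates.values() if c.f1 >= best_f1 - 0.005]
        if len(tied) > 1:
            # among ties the measured-faster family must win
            assert sel.fit_predict_seconds == min(c.fit_predict_seconds for c in tied)
        report = sel.report()
        assert len(report) == 2 and report["chosen"].sum() == 1

    def test_dominant_family_chosen_regardless_of_time(self):
        table, labels, subjects = planted_dataset(sep=2.0, n_noise=2, seed=12)
        sel = select_node_model(
            table, labels, subjects,
            families=("logreg", "dtree"), budget=0, max_candidates=3,
        )
        best_f1 = max(c.f1 for c in sel.candidates.values())
        assert sel.f1 >= best_f1 - 0.005
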