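"""Grouped LOOCV, hyperparameter optimization and feature-table assembly."""

import numpy as np
import pandas as pd
import pytest

from paflz.harness import (
    DEFAULT_KNN_METRICS,
    FeatureSelector,
    KnnSpace,
    SvmSpace,
    bayes_optimize,
    build_feature_table,
    loocv_evaluate,
    resolve_hyperparameters,
)


def _table(features, labels, patients=None):
    n = len(labels)
    if patients is None:
        patients = [f"p{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n)],
            "patient_id": patients,
            "label": labels,
        }
    )
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] != n:
        features = features.T
    for j in range(features.shape[1]):
        df[f"f{j}"] = features[:, j]
    return df


def _random_table(rng, n_patients=20, n_features=2):
    labels = ["PAF" if i % 2 else "control" for i in range(n_patients)]
    return _table(rng.normal(size=(n_patients, n_features)), labels)


KNN1 = {"family": "knn", "k": 1, "metric": "euclidean"}


def test_space_cardinalities():
    assert KnnSpace().size == 500
    assert len(KnnSpace().ks) == 50
    assert len(DEFAULT_KNN_METRICS) == 10
    assert SvmSpace().size == 153


def test_separable_feature_classified_perfectly():
    labels = ["PAF"] * 4 + ["control"] * 4
    table = _table([1.0, 1.1, 0.9, 1.05, 0.0, 0.1, -0.1, 0.05], labels)
    res = loocv_evaluate(table, KNN1)
    assert res.accuracy == 1.0
    assert res.sensitivity == 1.0
    assert res.specificity == 1.0
    assert res.patient_accuracy == 1.0


def test_hand_built_confusion_matrix():
    """1-NN geometry forcing predictions [PAF, PAF, ctrl, ctrl] against
    truth [PAF, ctrl, PAF, ctrl]: accuracy = sensitivity = specificity = 0.5."""
    table = _table(
        [0.0, 1.1, 1.0, 2.5],
        ["PAF", "control", "PAF", "control"],
    )
    res = loocv_evaluate(table, KNN1, standardize=False)
    assert res.accuracy == 0.5
    assert res.sensitivity == 0.5
    assert res.specificity == 0.5


def test_shuffled_labels_score_at_chance(rng):
    """Mean LOOCV accuracy over label permutations sits at chance level.

    The table is large enough (60 records) that the leave-one-out class
    imbalance bias (training folds lean 29-vs-30 against the held-out
    record's class) is small against the permutation standard error.
    """
    base = _random_table(rng, n_patients=60)
    model = {"family": "knn", "k": 5, "metric": "euclidean"}
    accs = []
    for _ in range(20):
        t = base.copy()
        t["label"] = rng.permutation(t["label"].to_numpy())
        if t.groupby("label")["patient_id"].nunique().min() < 2:
            continue
        accs.append(loocv_evaluate(t, model).accuracy)
    mean = np.mean(accs)
    se = np.std(accs, ddof=1) / np.sqrt(len(accs))
    assert abs(mean - 0.5) < 3 * max(se, 0.02)


def test_single_class_training_fold_is_an_error():
    table = _table(
        [0.0, 1.0, 2.0, 3.0],
        ["PAF", "PAF", "control", "control"],
        patients=["a", "a", "b", "c"],
    )
    # removing patients b or c still leaves both classes, but removing "a"
    # (both PAF records) leaves a single-class training set
    with pytest.raises(ValueError, match="single-class|>= 2 patients"):
        loocv_evaluate(table, KNN1)


def test_svm_models_run(rng):
    table = _random_table(rng, n_patients=12)
    res = loocv_evaluate(
        table, {"family": "svm", "kernel": "rbf", "outlier_fraction": 0.3}
    )
    assert 0.0 <= res.accuracy <= 1.0


def test_collapsed_space_equals_direct_evaluation(rng):
    table = _random_table(rng)
    space = KnnSpace(ks=(3,), metrics=("cityblock",))
    res = bayes_optimize(table, space, n_iter=10, seed=0)
    direct = loocv_evaluate(
        table, {"family": "knn", "k": 3, "metric": "cityblock"}
    )
    assert res.accuracy == direct.accuracy
    assert res.params == {"family": "knn", "k": 3, "metric": "cityblock"}


def test_optimizer_matches_exhaustive_minimum(rng):
    table = _random_table(rng, n_patients=14)
    space = KnnSpace(ks=(1, 3, 5, 7, 9), metrics=("euclidean", "cityblock"))
    res = bayes_optimize(table, space, n_iter=space.size, seed=1)
    best = max(
        loocv_evaluate(table, c).accuracy for c in space.candidates()
    )
    assert res.accuracy == best


def test_smbo_deterministic_and_prefix_monotone(rng):
    table = _random_table(rng, n_patients=16, n_features=3)
    space = KnnSpace(ks=tuple(range(1, 16, 2)), metrics=DEFAULT_KNN_METRICS[:5])
    a = bayes_optimize(table, space, n_iter=15, seed=7)
    b = bayes_optimize(table, space, n_iter=15, seed=7)
    assert [t[1] for t in a.trace] == [t[1] for t in b.trace]
    longer = bayes_optimize(table, space, n_iter=25, seed=7)
    assert longer.accuracy >= a.accuracy
    assert [t[1] for t in longer.trace[:15]] == [t[1] for t in a.trace]


def test_resolve_hyperparameters_componentwise_mode():
    single = [{"k": 9, "metric": "cosine"}]
    assert resolve_hyperparameters(single) == single[0]
    optima = [
        {"k": 5, "metric": "euclidean"},
        {"k": 5, "metric": "cityblock"},
        {"k": 7, "metric": "euclidean"},
    ]
    assert resolve_hyperparameters(optima) == {"k": 5, "metric": "euclidean"}


def test_resolve_hyperparameters_mode_absent_falls_back():
    # k values all distinct (tie -> first seen, 5); metric mode is
    # cityblock; the combination (5, cityblock) is not among the optima
    optima = [
        {"k": 5, "metric": "euclidean"},
        {"k": 7, "metric": "cityblock"},
        {"k": 9, "metric": "cityblock"},
    ]
    with pytest.warns(UserWarning, match="mode"):
        got = resolve_hyperparameters(optima)
    assert got == optima[0]


def _tidy_features(rng, record_ids, leads, cgs, cxs, fs=500):
    rows = []
    for rid in record_ids:
        for lead in leads:
            for cg in cgs:
                for cx in cxs:
                    rows.append(
                        dict(record_id=rid, lead=lead, cg=cg, cx=cx,
                             fs=fs, value=float(rng.random()))
                    )
    return pd.DataFrame(rows)


def _cohort_frame(n=6):
    rows = []
    for i in range(n):
        arm = "case" if i < n // 2 else "control"
        rows.append(
            dict(record_id=f"r{i}", patient_id=f"p{i}", arm=arm,
                 sex="M", age_group="60-69")
        )
    return pd.DataFrame(rows)


def test_feature_table_column_counts(rng):
    from paflz.synth import LEAD_NAMES

    cohort = _cohort_frame()
    rids = cohort["record_id"].tolist()
    cgs, cxs = ("TC", "KM", "FD", "BD"), ("LZ76", "LZ78", "Ti")
    feats = _tidy_features(rng, rids, LEAD_NAMES, cgs, cxs)
    meta = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "age": 60.0,
            "sex": "F",
        }
    )
    # all 12 leads for one cg x cx
    t = build_feature_table(
        feats, cohort, FeatureSelector(leads="all", cg="TC", cx="LZ76")
    )
    assert len(t.columns) == 3 + 12
    # all 12 cg x cx combinations on one lead
    t = build_feature_table(
        feats, cohort, FeatureSelector(leads=("II",), cg=cgs, cx=cxs)
    )
    assert len(t.columns) == 3 + 12
    # demographics add exactly two columns
    t2 = build_feature_table(
        feats, cohort, FeatureSelector(leads=("II",), cg=cgs, cx=cxs),
        include_demographics=True, metadata=meta,
    )
    assert len(t2.columns) == len(t.columns) + 2
    assert set(t2["sex"]) == {1.0}


def test_feature_table_missing_value_names_record(rng):
    cohort = _cohort_frame()
    feats = _tidy_features(
        rng, cohort["record_id"].tolist()[:-1], ("II",), ("TC",), ("LZ76",)
    )
    with pytest.raises(ValueError, match="r5"):
        build_feature_table(
            feats, cohort, FeatureSelector(leads=("II",), cg="TC", cx="LZ76")
        )
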