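"""Metrics against independent oracles; training/prediction contracts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from rgenekit.balancing import LabeledDataset
from rgenekit.model_eval import (
    ConfusionMatrix,
    EvalReport,
    LearnerSpec,
    ModelArtifact,
    confusion,
    cross_validate,
    evaluate_holdout,
    metric_mcc,
    metric_roc_area,
    metric_sn_sp_acc,
    predict,
    train,
)
from rgenekit.sequence_io import NEGATIVE_LABEL, POSITIVE_LABEL


def separable_toy(n_per_class: int = 50, seed: int = 0) -> LabeledDataset:
    rng = np.random.default_rng(seed)
    pos = rng.normal(loc=1.0, scale=0.05, size=(n_per_class, 2))
    neg = rng.normal(loc=0.0, scale=0.05, size=(n_per_class, 2))
    ids = [f"p{i}" for i in range(n_per_class)] + [f"n{i}" for i in range(n_per_class)]
    features = pd.DataFrame(np.vstack([pos, neg]), index=ids, columns=["x", "y"])
    labels = pd.Series([POSITIVE_LABEL] * n_per_class + [NEGATIVE_LABEL] * n_per_class, index=ids)
    return LabeledDataset(features, labels)


# ----------------------------------------------------------------- metrics

class TestConfusion:
    def test_all_correct(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 0, 2, 0)

    def test_all_flipped(self):
        cm = confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert (cm.tp, cm.tn) == (0, 0) and (cm.fn, cm.fp) == (2, 2)

    def test_random_case_matches_hand_count(self, rng):
        labels = rng.integers(0, 2, size=100)
        preds = rng.integers(0, 2, size=100)
        cm = confusion(labels, preds)
        tp = sum(1 for l, p in zip(labels, preds) if l == 1 and p == 1)
        fn = sum(1 for l, p in zip(labels, preds) if l == 1 and p == 0)
        tn = sum(1 for l, p in zip(labels, preds) if l == 0 and p == 0)
        fp = sum(1 for l, p in zip(labels, preds) if l == 0 and p == 1)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (tp, fn, tn, fp)
        assert cm.m == 100


class TestSnSpAcc:
    def test_perfect_classifier(self):
        assert metric_sn_sp_acc(ConfusionMatrix(10, 0, 10, 0)) == (1.0, 1.0, 100.0)

    def test_balanced_rates(self):
        sn, sp, acc = metric_sn_sp_acc(ConfusionMatrix(tp=831, fn=169, tn=687, fp=313))
        assert sn == pytest.approx(0.831)
        assert sp == pytest.approx(0.687)
        assert acc == pytest.approx(75.9)

    def test_totally_wrong_classifier(self):
        sn, sp, acc = metric_sn_sp_acc(ConfusionMatrix(0, 10, 0, 10))
        assert (sn, sp, acc) == (0.0, 0.0, 0.0)

    def test_empty_class_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="SN undefined"):
            sn, sp, _ = metric_sn_sp_acc(ConfusionMatrix(0, 0, 5, 5))
        assert math.isnan(sn) and sp == 0.5

    def test_balanced_evaluation_identity(self):
        # with equal class sizes, Acc == 100*(SN+SP)/2 exactly
        cm = ConfusionMatrix(tp=831, fn=169, tn=687, fp=313)
        sn, sp, acc = metric_sn_sp_acc(cm)
        assert acc == pytest.approx(100.0 * (sn + sp) / 2.0)


class TestMcc:
    def test_perfect_classifier(self):
        assert metric_mcc(ConfusionMatrix(10, 0, 10, 0)) == 1.0

    def test_benchmark_rates(self):
        assert round(metric_mcc(ConfusionMatrix(tp=831, fn=169, tn=687, fp=313)), 3) == 0.523

    def test_exhaustive_grid_matches_independent_formula(self):
        # sklearn computes MCC from label vectors: an independent route
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            cm = ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)
            labels = [1] * (tp + fn) + [0] * (tn + fp)
            preds = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            if not labels:
                continue
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if denom == 0:
                with pytest.warns(UserWarning):
                    assert metric_mcc(cm) == 0.0
            else:
                assert metric_mcc(cm) == pytest.approx(matthews_corrcoef(labels, preds))

    def test_sign_symmetry(self, rng):
        labels = rng.integers(0, 2, size=60)
        preds = rng.integers(0, 2, size=60)
        direct = metric_mcc(confusion(labels, preds))
        flipped = metric_mcc(confusion(1 - labels, 1 - preds))
        assert direct == pytest.approx(flipped)
        assert -1.0 <= direct <= 1.0


class TestRocArea:
    def test_perfect_ranking(self):
        assert metric_roc_area([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores(self):
        assert metric_roc_area([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_all_pairs_concordance_oracle(self, rng):
        labels = np.array([1] * 10 + [0] * 10)
        scores = np.round(rng.random(20), 1)  # rounding forces ties
        # O(n^2) oracle: concordant pairs + half credit for ties
        total = 0.0
        for sp in scores[labels == 1]:
            for sn in scores[labels == 0]:
                total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        oracle = total / 100.0
        assert metric_roc_area(labels, scores) == pytest.approx(oracle)
        assert metric_roc_area(labels, scores) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            metric_roc_area([1, 1], [0.1, 0.9])


# ----------------------------------------------------------- train/predict

class TestTrainPredict:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        ds = separable_toy()
        model = train(ds, seed=0)
        preds = predict(model, ds.features)
        assert (preds["label"].to_numpy() == ds.y()).all()

    def test_same_seed_gives_identical_predictions(self):
        ds = separable_toy()
        p1 = predict(train(ds, seed=5), ds.features)
        p2 = predict(train(ds, seed=5), ds.features)
        pd.testing.assert_frame_equal(p1, p2)

    def test_scores_invariant_to_row_order(self, rng):
        ds = separable_toy()
        model = train(ds, seed=0)
        shuffled = ds.features.sample(frac=1.0, random_state=1)
        p_orig = predict(model, ds.features)
        p_shuf = predict(model, shuffled)
        pd.testing.assert_frame_equal(p_orig.loc[shuffled.index], p_shuf)

    def test_empty_feature_matrix_gives_empty_output(self):
        ds = separable_toy()
        model = train(ds, seed=0)
        out = predict(model, ds.features.iloc[:0])
        assert len(out) == 0 and list(out.columns) == ["score", "label"]

    def test_schema_mismatch_names_columns(self):
        ds = separable_toy()
        model = train(ds, seed=0)
        bad = ds.features.rename(columns={"y": "z"})
        with pytest.raises(ValueError, match="missing columns \\['y'\\].*extra columns \\['z'\\]"):
            predict(model, bad)

    def test_single_class_training_is_an_error(self):
        ds = separable_toy()
        pos_only = ds.subset([i for i in ds.ids if i.startswith("p")])
        with pytest.raises(ValueError, match="both classes"):
            train(pos_only)

    def test_nan_features_are_an_error(self):
        ds = separable_toy()
        ds.features.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(ds)

    def test_artifact_round_trip(self, tmp_path):
        ds = separable_toy()
        model = train(ds, seed=2)
        model.save(tmp_path / "model.joblib")
        back = ModelArtifact.load(tmp_path / "model.joblib")
        assert back.feature_names == model.feature_names
        pd.testing.assert_frame_equal(predict(back, ds.features), predict(model, ds.features))

    def test_instance_weights_are_honored(self):
        # weight one class to near-zero: the fit should then call everything
        # by the dominant class on ambiguous points
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 1)), index=[f"i{k}" for k in range(40)], columns=["x"])
        y = pd.Series([POSITIVE_LABEL] * 20 + [NEGATIVE_LABEL] * 20, index=X.index)
        w = pd.Series([1000.0] * 20 + [1e-6] * 20, index=X.index)
        model = train(LabeledDataset(X, y, w), seed=0)
        preds = predict(model, X)
        assert preds["label"].mean() > 0.9


class TestCrossValidate:
    def test_pooled_confusion_covers_every_instance(self):
        ds = separable_toy(30)
        report = cross_validate(ds, k=5, seed=0)
        assert report.confusion.m == len(ds)
        assert report.protocol == "cv5"

    def test_leave_one_out_boundary(self):
        ds = separable_toy(5)
        report = cross_validate(ds, k=5, seed=0)
        assert report.confusion.m == 10

    def test_same_seed_gives_identical_report(self):
        ds = separable_toy(20)
        r1 = cross_validate(ds, k=4, seed=3)
        r2 = cross_validate(ds, k=4, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_k_above_class_count_is_an_error(self):
        with pytest.raises(ValueError, match="smallest class"):
            cross_validate(separable_toy(5), k=6)


def test_holdout_report_fields():
    ds = separable_toy(25)
    model = train(ds, seed=0)
    report = evaluate_holdout(model, ds)
    assert report.protocol == "holdout"
    assert report.acc == pytest.approx(100.0)
    assert report.mcc == pytest.approx(1.0)
    assert report.roc_area == pytest.approx(1.0)


def test_eval_report_json_round_trip(tmp_path):
    report = EvalReport.from_predictions(
        np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1]), "holdout", seed=1
    )
    path = tmp_path / "report.json"
    report.to_json(path)
    import json

    data = json.loads(path.read_text())
    assert data["confusion"] == {"tp": 2, "fn": 0, "tn": 2, "fp": 0}
    assert data["acc"] == 100.0
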