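import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from histo3c.evaluation import (
    ConfusionCounts,
    format_mean_std,
    image_accuracy,
    patient_accuracy,
    patient_scores,
    report_markdown,
    run_experiment,
    run_trial,
    se_pr_f1,
    split_patients,
    train_classifier,
)

from conftest import make_meta


def metas_for(n_benign, n_malignant, images_each=1):
    metas = []
    for i in range(n_benign):
        for j in range(images_each):
            metas.append(make_meta(f"b{i}-{j}", f"pb{i}", "benign"))
    for i in range(n_malignant):
        for j in range(images_each):
            metas.append(make_meta(f"m{i}-{j}", f"pm{i}", "malignant"))
    return metas


class TestSplit:
    def test_stratified_counts(self):
        plan = split_patients(metas_for(10, 10), 0.7, seed=1)
        train_b = {p for p in plan.train_patients if p.startswith("pb")}
        train_m = {p for p in plan.train_patients if p.startswith("pm")}
        assert len(train_b) == len(train_m) == 7
        assert len(plan.test_patients) == 6

    def test_deterministic(self):
        metas = metas_for(5, 9)
        assert split_patients(metas, seed=3) == split_patients(metas, seed=3)
        assert split_patients(metas, seed=3) != split_patients(metas, seed=4)

    def test_patient_disjoint_over_many_seeds(self):
        metas = metas_for(6, 14, images_each=2)
        all_patients = {m.patient_id for m in metas}
        for seed in range(100):
            plan = split_patients(metas, seed=seed)
            assert not plan.train_patients & plan.test_patients
            assert plan.train_patients | plan.test_patients == all_patients

    def test_each_class_keeps_a_test_patient(self):
        plan = split_patients(metas_for(2, 20), 0.9, seed=0)
        assert any(p.startswith("pb") for p in plan.test_patients)
        assert any(p.startswith("pm") for p in plan.test_patients)

    def test_single_patient_class_errors(self):
        with pytest.raises(ValueError, match="benign"):
            split_patients(metas_for(1, 5))


class TestClassifier:
    def test_separable_clusters_fit(self, rng):
        X = np.concatenate([rng.normal(0, 0.1, (20, 1)), rng.normal(5, 0.1, (20, 1))])
        y = ["benign"] * 20 + ["malignant"] * 20
        model = train_classifier(X, y)
        assert (model.predict(X) == np.array(y)).all()

    def test_default_hyperparameters(self, rng):
        X = rng.normal(size=(10, 2))
        y = ["benign"] * 5 + ["malignant"] * 5
        svc = train_classifier(X, y).named_steps["svm"]
        assert svc.C == 2.0 and svc.gamma == 1.0

    def test_conflicting_duplicate_rows_still_fit(self):
        X = np.ones((6, 2))
        y = ["benign", "malignant"] * 3
        model = train_classifier(X, y)
        assert model.predict(X).shape == (6,)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(np.ones((4, 1)), ["benign"] * 4)

    def test_scaling_depends_only_on_training_rows(self, rng):
        X = rng.normal(size=(30, 3))
        y = ["benign"] * 15 + ["malignant"] * 15
        model = train_classifier(X, y)
        probe = rng.normal(size=(5, 3)) * 100  # wild test rows
        before = model.predict(probe)
        model2 = train_classifier(X, y)  # refit; nothing about probe entered either fit
        assert (before == model2.predict(probe)).all()


class TestMetrics:
    def test_image_accuracy_examples(self):
        assert image_accuracy(ConfusionCounts(TP=9, TN=0, FP=0, FN=1)) == pytest.approx(0.9)
        assert image_accuracy(ConfusionCounts(5, 5, 0, 0)) == 1.0
        with pytest.raises(ValueError):
            image_accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_patient_accuracy_worked_example(self):
        # patient A: 3/4 correct, patient B: 1/1
        scores = patient_scores(
            ["A", "A", "A", "A", "B"],
            ["benign"] * 5,
            ["benign", "benign", "benign", "malignant", "benign"],
        )
        assert scores == {"A": 0.75, "B": 1.0}
        assert patient_accuracy(scores) == pytest.approx(0.875)

    def test_patient_accuracy_edge_cases(self):
        assert patient_accuracy({"A": 1.0, "B": 1.0}) == 1.0
        assert patient_accuracy({"A": 0.6}) == pytest.approx(0.6)
        with pytest.raises(ValueError):
            patient_accuracy({})

    def test_se_pr_f1_worked_example(self):
        se, pr, f1 = se_pr_f1(ConfusionCounts(TP=8, TN=0, FP=3, FN=2))
        assert se == pytest.approx(0.8)
        assert pr == pytest.approx(8 / 11)
        assert f1 == pytest.approx(16 / 21)

    def test_perfect_counts(self):
        assert se_pr_f1(ConfusionCounts(5, 3, 0, 0)) == (1.0, 1.0, 1.0)

    def test_undefined_metrics_are_missing_not_zero(self):
        se, pr, f1 = se_pr_f1(ConfusionCounts(TP=0, TN=4, FP=0, FN=0))
        assert se is None and pr is None

    @given(
        tp=st.integers(1, 50), tn=st.integers(0, 50),
        fp=st.integers(1, 50), fn=st.integers(1, 50),
    )
    @settings(derandomize=True, max_examples=50)
    def test_f1_is_harmonic_mean_and_accuracy_identity(self, tp, tn, fp, fn):
        counts = ConfusionCounts(tp, tn, fp, fn)
        se, pr, f1 = se_pr_f1(counts)
        assert f1 == pytest.approx(2 * se * pr / (se + pr))
        assert image_accuracy(counts) == pytest.approx((tp + tn) / (tp + tn + fp + fn))


def test_format_mean_std():
    assert format_mean_std(0.9412, 0.0219) == "94.12 ± 2.19"
    assert format_mean_std(1.0, 0.0) == "100.00 ± 0.00"


def feature_table(rng, n_benign=5, n_malignant=9, images_each=4, separation=3.0):
    rows = []
    for cls, n, mu in (("benign", n_benign, 0.0), ("malignant", n_malignant, separation)):
        for i in range(n):
            for j in range(images_each):
                rows.append({
                    "image_id": f"{cls[0]}{i}-{j}",
                    "patient_id": f"p{cls[0]}{i}",
                    "class_label": cls,
                    "magnification": "200X",
                    "f_000": rng.normal(mu, 1.0),
                    "f_001": rng.normal(-mu, 1.0),
                })
    return pd.DataFrame(rows)


class TestExperiment:
    def test_separable_table_near_perfect(self, rng):
        report = run_experiment(feature_table(rng, separation=6.0), seed=0)
        acc = report[report.metric == "image_accuracy"]["mean"].iloc[0]
        assert acc > 0.95

    def test_five_trials_aggregated(self, rng):
        report = run_experiment(feature_table(rng), n_trials=5, seed=0)
        assert (report["n_trials"] == 5).all()
        assert set(report["metric"]) == {
            "image_accuracy", "patient_accuracy", "sensitivity", "precision", "f1"
        }

    def test_formatting_matches_protocol(self, rng):
        report = run_experiment(feature_table(rng), seed=0)
        import re
        for s in report["formatted"]:
            assert re.fullmatch(r"\d+\.\d{2} ± \d+\.\d{2}", s)

    def test_trial_patient_disjointness_and_null_effect(self, rng):
        table = feature_table(rng, separation=0.0)
        res = run_trial(table, seed=0)
        # with no signal, accuracy should sit near the majority-class rate
        assert 0.3 <= res["image_accuracy"] <= 1.0
        report = run_experiment(table, seed=0)
        acc = report[report.metric == "image_accuracy"]["mean"].iloc[0]
        assert abs(acc - 9 / 14) < 0.25  # binomial noise around the malignant fraction

    def test_always_malignant_stub(self, rng):
        """A degenerate predictor: Se = 1 and accuracy = malignant fraction."""
        table = feature_table(rng)
        y_true = table["class_label"].to_numpy()
        y_pred = np.array(["malignant"] * len(table))
        counts = ConfusionCounts.from_labels(y_true, y_pred)
        se, _, _ = se_pr_f1(counts)
        assert se == 1.0
        assert image_accuracy(counts) == pytest.approx((y_true == "malignant").mean())

    def test_unsplittable_magnification_skipped(self, rng, caplog):
        table = feature_table(rng, n_benign=1)
        with caplog.at_level("WARNING"):
            report = run_experiment(table, seed=0)
        assert report.empty

    def test_report_markdown_renders(self, rng):
        report = run_experiment(feature_table(rng), seed=0)
        md = report_markdown(report, "STUB", "rgb")
        assert "| Magnification |" in md and "200X" in md
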