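"""Fold planning, cross-validated evaluation, metric identities, persistence."""

import numpy as np
import pytest

from raackit import (
    ProteinSequence,
    SyntheticSpec,
    TupleSpec,
    confusion_metrics,
    cross_validate,
    dataset_from_sequences,
    build_dataset,
    generate_synthetic,
    load_model,
    make_folds,
    roc_auc,
    save_model,
    train_full,
    write_fasta,
)
from raackit.ml import _midranks


def planted_dataset(scheme, effect, seed, n=50, spec=None):
    pos, neg = generate_synthetic(SyntheticSpec(
        n_pos=n, n_neg=n, effect=effect, seed=seed))
    return dataset_from_sequences(pos, neg, scheme,
                                  spec or TupleSpec(2, 0, 0))


class TestConfusionMetrics:
    def test_worked_confusion_example(self):
        m = confusion_metrics(tp=40, tn=35, fp=15, fn=10)
        assert m["Sn"] == pytest.approx(0.8)
        assert m["Sp"] == pytest.approx(0.7)
        assert m["Acc"] == pytest.approx(0.75)
        expected_mcc = (40 * 35 - 15 * 10) / np.sqrt(
            (40 + 15) * (40 + 10) * (35 + 15) * (35 + 10))
        assert m["MCC"] == pytest.approx(expected_mcc)

    def test_zero_denominator_convention(self):
        assert confusion_metrics(0, 0, 0, 10)["MCC"] == 0.0

    def test_mcc_bounded(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0:
                continue
            assert abs(confusion_metrics(tp, tn, fp, fn)["MCC"]) <= 1 + 1e-12

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(50):
            y = rng.choice([-1, 1], size=30)
            p = rng.choice([-1, 1], size=30)
            tp = int(((p == 1) & (y == 1)).sum())
            tn = int(((p == -1) & (y == -1)).sum())
            fp = int(((p == 1) & (y == -1)).sum())
            fn = int(((p == -1) & (y == 1)).sum())
            ours = confusion_metrics(tp, tn, fp, fn)["MCC"]
            assert ours == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        roc, auc = roc_auc([3, 2, 1, 0], [1, 1, -1, -1])
        assert auc == 1.0
        assert tuple(roc[0]) == (0, 0) and tuple(roc[-1]) == (1, 1)

    def test_all_ties_give_half(self):
        _, auc = roc_auc([5, 5, 5, 5], [1, 1, -1, -1])
        assert auc == 0.5

    def test_curve_monotone_and_matches_trapezoid(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 60))
            scores = rng.choice(np.round(rng.normal(size=6), 2), size=n)
            labels = rng.choice([-1, 1], size=n)
            if len(set(labels)) < 2:
                continue
            roc, auc = roc_auc(scores, labels)
            assert np.all(np.diff(roc[:, 0]) >= 0)
            assert np.all(np.diff(roc[:, 1]) >= 0)
            trap = np.trapezoid(roc[:, 1], roc[:, 0])
            assert trap == pytest.approx(auc, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            scores = rng.normal(size=40)
            labels = rng.choice([-1, 1], size=40)
            if len(set(labels)) < 2:
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(roc_auc_score(labels, scores),
                                        abs=1e-12)

    def test_label_swap_maps_auc(self, rng):
        for _ in range(50):
            scores = rng.normal(size=30)
            labels = rng.choice([-1, 1], size=30)
            if len(set(labels)) < 2:
                continue
            _, auc = roc_auc(scores, labels)
            _, swapped = roc_auc(scores, -labels)
            assert swapped == pytest.approx(1 - auc, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], [1, 1])

    def test_midranks(self):
        assert list(_midranks(np.array([10.0, 20.0, 20.0, 30.0]))) == \
            [1.0, 2.5, 2.5, 4.0]


class TestFolds:
    def test_perfect_stratification(self):
        labels = [1] * 5 + [-1] * 5
        plan = make_folds(labels, n_folds=5, seed=1)
        for fold in range(5):
            members = [l for l, a in zip(labels, plan.assignments)
                       if a == fold]
            assert sorted(members) == [-1, 1]

    def test_loo_gives_singletons(self):
        plan = make_folds([1] * 5 + [-1] * 5, loo=True)
        assert plan.n_folds == 10
        assert sorted(plan.assignments) == list(range(10))

    def test_deterministic_per_seed(self):
        labels = [1] * 10 + [-1] * 10
        a = make_folds(labels, 5, seed=3).assignments
        b = make_folds(labels, 5, seed=3).assignments
        c = make_folds(labels, 5, seed=4).assignments
        assert a == b and a != c

    def test_stratification_near_proportional(self):
        labels = [1] * 9 + [-1] * 6
        plan = make_folds(labels, n_folds=3, seed=0)
        for fold in range(3):
            pos = sum(1 for l, a in zip(labels, plan.assignments)
                      if a == fold and l == 1)
            assert pos == 3

    def test_too_many_folds_suggests_loo(self):
        with pytest.raises(ValueError, match="leave-one-out"):
            make_folds([1, 1, -1, -1], n_folds=3)


class TestCrossValidate:
    def test_perfect_separation_limit(self, registry):
        scheme = registry.get("t1", 8)
        dataset = planted_dataset(scheme, effect=50.0, seed=0, n=25)
        plan = make_folds(dataset.labels, 5, seed=0)
        report = cross_validate(dataset, plan, "svm")
        assert report.Acc == 1.0 and report.MCC == 1.0 and report.AUC == 1.0

    def test_permutation_null_auc(self, registry):
        scheme = registry.get("t1", 8)
        dataset = planted_dataset(scheme, effect=2.0, seed=5, n=100)
        rng = np.random.default_rng(7)
        dataset.labels = rng.permutation(dataset.labels)
        plan = make_folds(dataset.labels, 5, seed=7)
        report = cross_validate(dataset, plan, "svm")
        assert 0.35 <= report.AUC <= 0.65

    @pytest.mark.parametrize("clf", ["svm", "knn", "rf"])
    def test_all_classifiers_run_and_pool_once(self, registry, clf):
        scheme = registry.get("t1", 4)
        dataset = planted_dataset(scheme, effect=3.0, seed=1, n=20)
        plan = make_folds(dataset.labels, 4, seed=1)
        report = cross_validate(dataset, plan, clf)
        assert report.TP + report.TN + report.FP + report.FN == 40
        assert len(report.per_fold) == 4
        assert sum(f["n_test"] for f in report.per_fold) == 40

    def test_unknown_classifier_lists_supported(self, registry):
        scheme = registry.get("t1", 4)
        dataset = planted_dataset(scheme, effect=2.0, seed=1, n=10)
        plan = make_folds(dataset.labels, 2, seed=1)
        with pytest.raises(ValueError, match="knn.*rf.*svm|svm"):
            cross_validate(dataset, plan, "mlp")

    def test_label_swap_negates_mcc_at_fixed_predictions(self, registry):
        # negating the true labels while keeping the pooled predictions
        # fixed swaps TP<->FP and TN<->FN, negating MCC
        scheme = registry.get("t1", 8)
        dataset = planted_dataset(scheme, effect=2.0, seed=2, n=20)
        plan = make_folds(dataset.labels, 4, seed=2)
        report = cross_validate(dataset, plan, "knn")
        swapped = confusion_metrics(tp=report.FP, tn=report.FN,
                                    fp=report.TP, fn=report.TN)
        assert swapped["MCC"] == pytest.approx(-report.MCC, abs=1e-12)

    def test_report_serializes(self, registry):
        scheme = registry.get("t1", 4)
        dataset = planted_dataset(scheme, effect=2.0, seed=3, n=10)
        plan = make_folds(dataset.labels, 2, seed=3)
        report = cross_validate(dataset, plan, "rf")
        d = report.to_dict()
        assert d["schema_version"] == 1
        assert "Sn=" in report.summary()


class TestDatasetBuilding:
    def test_labels_and_order(self, registry, tmp_path):
        pos, neg = generate_synthetic(SyntheticSpec(n_pos=5, n_neg=5, seed=1))
        pf, nf = tmp_path / "p.fa", tmp_path / "n.fa"
        write_fasta(pos, pf)
        write_fasta(neg, nf)
        scheme = registry.get("t1", 4)
        ds = build_dataset(pf, nf, scheme, TupleSpec(2, 0, 0))
        assert list(ds.labels) == [1] * 5 + [-1] * 5
        assert ds.features.row_ids == [s.id for s in pos + neg]

    def test_duplicate_ids_warned_not_fatal(self, registry, caplog):
        pos = [ProteinSequence("same", "ACDEFGHIKLMNPQRSTVWY")]
        neg = [ProteinSequence("same", "YWVTSRQPNMLKIHGFEDCA")]
        scheme = registry.get("t1", 4)
        with caplog.at_level("WARNING"):
            ds = dataset_from_sequences(pos, neg, scheme, TupleSpec(1, 0, 0))
        assert "duplicate ids" in caplog.text
        assert ds.n_rows == 2

    def test_empty_class_after_rejection_is_error(self, registry):
        pos = [ProteinSequence("p", "AC")]
        neg = [ProteinSequence("n", "ACDEFGHIKL")]
        scheme = registry.get("t1", 4)
        with pytest.raises(ValueError, match="class became empty|no extractable"):
            dataset_from_sequences(pos, neg, scheme, TupleSpec(3, 0, 1))


class TestModelPersistence:
    def test_round_trip_predictions(self, registry, tmp_path):
        scheme = registry.get("t1", 8)
        dataset = planted_dataset(scheme, effect=3.0, seed=4, n=20)
        clf = train_full(dataset, "svm", seed=4)
        path = tmp_path / "model.joblib"
        save_model(clf, path, metadata={"seed": 4})
        loaded, meta = load_model(path)
        X = dataset.features.values
        assert np.array_equal(loaded.predict(X), clf.predict(X))
        assert meta["seed"] == 4

    def test_tampered_model_rejected(self, registry, tmp_path):
        scheme = registry.get("t1", 4)
        dataset = planted_dataset(scheme, effect=2.0, seed=4, n=10)
        clf = train_full(dataset, "knn")
        path = tmp_path / "model.joblib"
        save_model(clf, path)
        path.write_bytes(path.read_bytes() + b"x")
        with pytest.raises(ValueError, match="hash mismatch"):
            load_model(path)

    def test_version_mismatch_rejected(self, registry, tmp_path):
        import json

        scheme = registry.get("t1", 4)
        dataset = planted_dataset(scheme, effect=2.0, seed=4, n=10)
        clf = train_full(dataset, "knn")
        path = tmp_path / "model.joblib"
        save_model(clf, path)
        meta_path = tmp_path / "model.joblib.meta.json"
        meta = json.loads(meta_path.read_text())
        meta["format_version"] = 99
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="format version"):
            load_model(path)

    def test_missing_sidecar_rejected(self, tmp_path):
        path = tmp_path / "model.joblib"
        path.write_bytes(b"data")
        with pytest.raises(ValueError, match="sidecar"):
            load_model(path)

    def test_rerun_with_same_seed_reproduces_report(self, registry):
        scheme = registry.get("t1", 8)
        reports = []
        for _ in range(2):
            dataset = planted_dataset(scheme, effect=2.0, seed=6, n=20)
            plan = make_folds(dataset.labels, 4, seed=6)
            reports.append(cross_validate(dataset, plan, "rf", seed=6))
        assert reports[0].to_json() == reports[1].to_json()
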