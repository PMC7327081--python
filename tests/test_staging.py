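import numpy as np
import pytest

from coexstage.io import STAGES
from coexstage.staging import (
    EvaluationReport,
    ProtocolConfig,
    StageClassifier,
    average_reports,
    confusion_matrix_predicted_by_annotated,
    evaluate,
    metrics_from_confusion,
    split_samples,
)


def _labels(counts, controls=0):
    labels = {}
    for stage, n in counts.items():
        for i in range(n):
            labels[f"T{stage}_{i}"] = stage
    for i in range(controls):
        labels[f"C_{i}"] = "control"
    return labels


class TestSplitSamples:
    @pytest.mark.parametrize("n,expected", [
        (100, (30, 40, 30)),
        (10, (3, 4, 3)),
        (11, (3, 5, 3)),  # remainder goes to training
    ])
    def test_fraction_rounding(self, n, expected):
        labels = _labels({s: n for s in STAGES})
        plan = split_samples(labels, seed=0)
        for stage in STAGES:
            got = (len(plan.reference[stage]), len(plan.training[stage]),
                   len(plan.test[stage]))
            assert got == expected

    def test_partitions_disjoint_and_exhaustive(self):
        labels = _labels({1: 13, 2: 21, 3: 10, 4: 37}, controls=5)
        plan = split_samples(labels, seed=3)
        for stage in STAGES:
            parts = [set(plan.reference[stage]), set(plan.training[stage]),
                     set(plan.test[stage])]
            assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
            assert parts[0] | parts[1] | parts[2] == {
                s for s, g in labels.items() if g == stage}

    def test_reproducible_and_seed_sensitive(self):
        labels = _labels({s: 40 for s in STAGES})
        a = split_samples(labels, seed=5)
        b = split_samples(labels, seed=5)
        c = split_samples(labels, seed=6)
        assert a.reference == b.reference and a.test == b.test
        assert a.reference != c.reference

    def test_small_stage_named_in_error(self):
        labels = _labels({1: 10, 2: 3, 3: 10, 4: 10})
        with pytest.raises(ValueError, match="stage 2"):
            split_samples(labels)

    def test_bad_fractions_rejected(self):
        labels = _labels({s: 10 for s in STAGES})
        with pytest.raises(ValueError, match="sum to 1"):
            split_samples(labels, fractions=(0.5, 0.6, 0.3))


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = {f"s{i}": 1 + i % 4 for i in range(40)}
        report = evaluate({s: g for s, g in truth.items()}, truth)
        assert report.accuracy == 1.0 and report.kappa == 1.0
        assert all(v == 1.0 for v in report.sensitivity.values())
        assert all(v == 1.0 for v in report.specificity.values())

    def test_single_class_collapse_gives_chance_and_zero_kappa(self):
        truth = {f"s{i}": 1 + i % 4 for i in range(40)}
        report = evaluate({s: 2 for s in truth}, truth)
        assert report.accuracy == pytest.approx(0.25)
        assert report.kappa == pytest.approx(0.0)

    def test_two_class_kappa_hand_value(self):
        # confusion [[8,2],[2,8]]: accuracy 0.8, p_e 0.5, kappa 0.6
        m = metrics_from_confusion(np.array([[8, 2], [2, 8]]), classes=(1, 2))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["kappa"] == pytest.approx(0.6)

    def test_random_confusions_against_direct_formulas(self, rng):
        """Sensitivity/specificity/accuracy/kappa vs independent hand formulas."""
        from sklearn.metrics import cohen_kappa_score

        for _ in range(25):
            m = rng.integers(0, 30, size=(4, 4))
            m[0, 0] += 1  # never fully empty
            got = metrics_from_confusion(m)
            total = m.sum()
            assert got["accuracy"] == pytest.approx(np.trace(m) / total)
            for i, stage in enumerate(STAGES):
                col = m[:, i].sum()
                row = m[i, :].sum()
                if col:
                    assert got["sensitivity"][stage] == pytest.approx(m[i, i] / col)
                tn = total - row - col + m[i, i]
                fp = row - m[i, i]
                assert got["specificity"][stage] == pytest.approx(tn / (tn + fp))
            # kappa cross-check: expand confusion into label pairs for sklearn
            pred, annot = [], []
            for i in range(4):
                for j in range(4):
                    pred += [i] * m[i, j]
                    annot += [j] * m[i, j]
            assert got["kappa"] == pytest.approx(cohen_kappa_score(pred, annot))

    def test_confusion_orientation_rows_are_predictions(self):
        m = confusion_matrix_predicted_by_annotated([1, 1, 2], [1, 3, 2])
        assert m[0, 0] == 1 and m[0, 2] == 1 and m[1, 1] == 1

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate({}, {"s": 1})

    def test_prediction_without_truth_rejected(self):
        with pytest.raises(ValueError, match="truth"):
            evaluate({"s1": 1}, {"s2": 1})


class TestStageClassifier:
    def _separable(self, n_per_class=12, seed=0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for stage in STAGES:
            block = np.zeros((n_per_class, 8))
            block[:, (stage - 1) * 2:(stage - 1) * 2 + 2] = 3.0
            X.append(block + 0.01 * rng.standard_normal(block.shape))
            y += [stage] * n_per_class
        return np.vstack(X), np.array(y)

    def test_separable_blocks_train_to_perfection(self):
        X, y = self._separable()
        clf = StageClassifier(cv_repeats=2, seed=0)
        clf.fit(X, y)
        assert np.array_equal(clf.predict(X), y)
        assert clf.cv_accuracy_ == pytest.approx(1.0)

    def test_shuffled_labels_hover_at_chance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 10))
        y = np.array([1 + i % 4 for i in range(80)])
        clf = StageClassifier(cv_repeats=3, seed=1)
        clf.fit(X, rng.permutation(y))
        # 3 Monte-Carlo standard errors of a 0.25 binomial over the CV pool
        se = np.sqrt(0.25 * 0.75 / 80)
        assert abs(clf.cv_accuracy_ - 0.25) < 3 * se + 0.05

    def test_same_seed_reproduces_fit(self):
        X, y = self._separable(seed=2)
        a = StageClassifier(cv_repeats=2, seed=7).fit(X, y)
        b = StageClassifier(cv_repeats=2, seed=7).fit(X, y)
        assert a.best_params_ == b.best_params_
        assert a.cv_accuracy_ == b.cv_accuracy_
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_layout_checksum_guard(self):
        X, y = self._separable()
        clf = StageClassifier(cv_repeats=2, seed=0)
        clf.fit(X, y, layout_checksum="abc")
        clf.predict(X, layout_checksum="abc")
        with pytest.raises(ValueError, match="layout"):
            clf.predict(X, layout_checksum="different")

    def test_unknown_backend_rejected(self):
        X, y = self._separable()
        with pytest.raises(ValueError, match="backend"):
            StageClassifier(backend="svm9000").fit(X, y)

    def test_all_backends_fit_and_predict(self):
        from coexstage.staging import BACKENDS
        X, y = self._separable()
        for backend in BACKENDS:
            clf = StageClassifier(backend=backend, cv_repeats=1, seed=0).fit(X, y)
            assert set(clf.predict(X)) <= set(STAGES)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        clf = StageClassifier(backend="rf", cv_repeats=5, seed=3)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()


class TestAveraging:
    def _report(self, acc, kappa):
        return EvaluationReport(confusion=np.eye(4, dtype=int),
                                sensitivity={s: acc for s in STAGES},
                                specificity={s: acc for s in STAGES},
                                accuracy=acc, kappa=kappa)

    def test_mean_of_iteration_metrics(self):
        avg = average_reports([self._report(0.8, 0.7), self._report(1.0, 0.9)])
        assert avg.accuracy == pytest.approx(0.9)
        assert avg.kappa == pytest.approx(0.8)
        assert avg.n_iterations == 2
        assert avg.metric_sd["accuracy"] == pytest.approx(np.std([0.8, 1.0], ddof=1))

    def test_confusion_counts_pool(self):
        avg = average_reports([self._report(1.0, 1.0)] * 3)
        assert np.array_equal(avg.confusion, 3 * np.eye(4, dtype=int))


class TestProtocolDeterminism:
    def test_same_master_seed_identical_reports(self, tiny_sim):
        from coexstage.staging import run_protocol
        cfg, expr, labels, truth = tiny_sim
        pc = ProtocolConfig(n_iterations=1, cv_repeats=2, master_seed=13)
        r1 = run_protocol(expr, labels, pc)
        r2 = run_protocol(expr, labels, pc)
        assert r1.accuracy == r2.accuracy and r1.kappa == r2.kappa
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_strict_split_runs_and_reports(self, tiny_sim):
        from coexstage.staging import run_protocol
        cfg, expr, labels, truth = tiny_sim
        pc = ProtocolConfig(n_iterations=1, cv_repeats=2, master_seed=3,
                            strict_split=True)
        report = run_protocol(expr, labels, pc)
        assert 0.0 <= report.accuracy <= 1.0
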