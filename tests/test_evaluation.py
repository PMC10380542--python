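import numpy as np
import pytest

from seedcascade import (
    SpectrumSet,
    classification_metrics,
    confusion_matrix,
    cross_variety_matrix,
    make_band_axis,
    pca_scores,
)
from seedcascade.errors import InvalidArgumentError
from seedcascade.evaluation import ConfusionMatrix


class TestConfusionMatrix:
    def test_all_correct_diagonal(self):
        y = ["a", "a", "b", "b", "c", "c"]
        cm = confusion_matrix(y, y, ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([2, 2, 2]))

    def test_constant_predictor_fills_first_column(self):
        t = ["a", "b", "c", "b"]
        cm = confusion_matrix(t, ["a"] * 4, ["a", "b", "c"])
        assert np.array_equal(cm.counts[:, 0], [1, 2, 1])
        assert cm.counts[:, 1:].sum() == 0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c", "d"]
        for _ in range(100):
            t = rng.choice(classes, size=30)
            p = rng.choice(classes, size=30)
            cm = confusion_matrix(t, p, classes)
            brute = np.zeros((4, 4), dtype=int)
            for i, ci in enumerate(classes):
                for j, cj in enumerate(classes):
                    brute[i, j] = sum(1 for a, b in zip(t, p) if a == ci and b == cj)
            assert np.array_equal(cm.counts, brute)

    def test_unknown_label_named_in_error(self):
        with pytest.raises(InvalidArgumentError, match="zzz"):
            confusion_matrix(["a", "zzz"], ["a", "a"], ["a", "b"])

    def test_tp_fp_fn_views(self):
        cm = ConfusionMatrix(np.array([[3, 1], [2, 4]]), ["x", "y"])
        assert cm.tp.tolist() == [3, 4]
        assert cm.fp.tolist() == [2, 1]
        assert cm.fn.tolist() == [1, 2]


class TestClassificationMetrics:
    def test_perfect_prediction_scores_one(self):
        cm = confusion_matrix(["a", "b", "c"], ["a", "b", "c"])
        rep = classification_metrics(cm)
        assert rep.accuracy == rep.macro_f1 == rep.micro_f1 == 1.0

    def test_micro_f1_equals_accuracy_on_random_tabulations(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            k = rng.integers(2, 6)
            counts = rng.integers(0, 10, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts, [f"c{i}" for i in range(k)])
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = classification_metrics(cm)
            assert rep.micro_f1 == pytest.approx(rep.accuracy, abs=1e-12)

    def test_two_class_macro_f1_hand_computation(self):
        # TP=(3,1), FP=(1,3), FN=(3,1): F1_0=0.6, F1_1=1/3, macro=7/15
        counts = np.array([[3, 3], [1, 1]])
        cm = ConfusionMatrix(counts, ["p", "q"])
        rep = classification_metrics(cm)
        assert rep.precision["p"] == pytest.approx(3 / 4)
        assert rep.recall["p"] == pytest.approx(3 / 6)
        assert rep.f1["p"] == pytest.approx(0.6)
        assert rep.f1["q"] == pytest.approx(1 / 3)
        assert rep.macro_f1 == pytest.approx(7 / 15)

    def test_degenerate_class_flagged_and_zeroed(self):
        counts = np.array([[2, 0], [1, 0]])  # nothing predicted as class 2
        cm = ConfusionMatrix(counts, ["a", "b"])
        with pytest.warns(RuntimeWarning):
            rep = classification_metrics(cm)
        assert rep.precision["b"] == 0.0
        assert "b" in rep.degenerate_classes

    def test_metrics_bounded_and_macro_one_iff_diagonal(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            counts = rng.integers(0, 8, size=(3, 3))
            counts[np.arange(3), np.arange(3)] += 1
            cm = ConfusionMatrix(counts, ["a", "b", "c"])
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = classification_metrics(cm)
            vals = [rep.accuracy, rep.macro_f1, rep.micro_f1, *rep.f1.values()]
            assert all(0 <= v <= 1 for v in vals)
            off_diag = counts.sum() - np.trace(counts)
            assert (rep.macro_f1 == 1.0) == (off_diag == 0)


class TestPCA:
    def test_single_direction_explains_everything(self):
        t = np.linspace(-1, 1, 12)
        X = np.outer(t, np.array([1.0, 2.0, -1.0, 0.5]))
        scores, frac = pca_scores(X, 2)
        assert frac[0] == pytest.approx(1.0)
        assert abs(frac[1]) < 1e-12

    def test_score_columns_orthogonal(self):
        X = np.random.default_rng(3).normal(size=(20, 6))
        scores, _ = pca_scores(X, 3)
        for i in range(3):
            for j in range(i + 1, 3):
                dot = abs(scores[:, i] @ scores[:, j])
                assert dot < 1e-8 * np.linalg.norm(scores[:, i]) * np.linalg.norm(scores[:, j])

    def test_matches_dense_eigensolver_up_to_sign(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            X = rng.normal(size=(6, 4))
            scores, frac = pca_scores(X, 2)
            Xc = X - X.mean(axis=0)
            evals, evecs = np.linalg.eigh(Xc.T @ Xc)
            order = np.argsort(evals)[::-1]
            ref = Xc @ evecs[:, order[:2]]
            for c in range(2):
                assert np.allclose(np.abs(scores[:, c]), np.abs(ref[:, c]), atol=1e-8)
            assert np.allclose(frac, (evals[order[:2]] / evals.sum()), atol=1e-10)

    def test_explained_fractions_sorted_and_bounded(self):
        X = np.random.default_rng(5).normal(size=(15, 8))
        _, frac = pca_scores(X, 4)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1 + 1e-12

    def test_constant_data_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pca_scores(np.ones((5, 4)), 1)

    def test_component_budget_enforced(self):
        with pytest.raises(InvalidArgumentError):
            pca_scores(np.random.default_rng(6).normal(size=(3, 4)), 3)


class _ConstantModel:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.array([self.label] * len(X), dtype=object)


class TestCrossVarietyMatrix:
    def _set(self, gm_labels):
        axis = make_band_axis("thz", 5, 0.3, 2.0)
        n = len(gm_labels)
        return SpectrumSet(
            np.zeros((n, 5)), axis, np.array(["v"] * n, dtype=object),
            np.array(gm_labels, dtype=object),
        )

    def test_single_variety_is_its_own_accuracy(self):
        sset = self._set(["GM", "GM", "non-GM", "non-GM"])
        mat, order = cross_variety_matrix({"v": _ConstantModel("GM")}, {"v": sset})
        assert mat.shape == (1, 1)
        assert mat[0, 0] == 0.5

    def test_constant_model_on_balanced_set_scores_half(self):
        sets = {
            "v1": self._set(["GM", "non-GM"] * 3),
            "v2": self._set(["GM", "non-GM"] * 5),
        }
        registry = {"v1": _ConstantModel("GM"), "v2": _ConstantModel("non-GM")}
        mat, order = cross_variety_matrix(registry, sets)
        assert order == ["v1", "v2"]
        assert np.allclose(mat, 0.5)
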