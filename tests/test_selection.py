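import numpy as np
import pytest

from seedcascade import (
    GuidedConfig,
    ModelSpec,
    TrainConfig,
    guided_identity_spectrum,
    guided_select,
    peaks_to_bands,
    selection_overlap,
    spa_select,
    train_model,
)
from seedcascade.errors import InvalidArgumentError
from seedcascade.selection import SelectionResult, spa_chain
from seedcascade.spectra import make_band_axis


@pytest.fixture(scope="module")
def planted_model(planted_binary):
    sset, planted = planted_binary
    model, hist = train_model(
        sset,
        sset.gm_labels,
        TrainConfig(epochs=60, learning_rate=1e-3, batch_size=16, rng_seed=9),
        ModelSpec.scaled(24, 2, scale=8),
    )
    assert hist.best_val_accuracy == 1.0
    return model


class TestGuidedOptimization:
    def test_loss_decreases_on_trained_model(self, planted_model):
        cfg = GuidedConfig(learning_rate=0.05, iterations=500, sparsity_weight=0.3, rng_seed=1)
        ident = guided_identity_spectrum(planted_model, 0, cfg)
        assert ident.final_loss < ident.loss_trace[0]
        assert len(ident.loss_trace) == 500

    def test_l1_term_increases_sparsity(self, planted_model):
        common = dict(learning_rate=0.05, iterations=500, rng_seed=2)
        with_l1 = guided_identity_spectrum(
            planted_model, 0, GuidedConfig(sparsity_weight=1.0, **common)
        )
        without = guided_identity_spectrum(
            planted_model, 0, GuidedConfig(sparsity_weight=0.0, **common)
        )
        frac = lambda x: np.mean(np.abs(x) < 0.01 * np.abs(x).max())
        assert frac(with_l1.x) > frac(without.x)

    def test_without_l1_target_score_does_not_decrease(self, planted_model):
        cfg = GuidedConfig(learning_rate=0.05, iterations=300, sparsity_weight=0.0, rng_seed=3)
        rng = np.random.default_rng(3)
        x0 = rng.uniform(0, 1, size=24)
        ident = guided_identity_spectrum(planted_model, 0, cfg, x0=x0)
        before = planted_model.predict_logits(x0[None, :])[0, 0]
        after = planted_model.predict_logits(ident.x[None, :])[0, 0]
        assert after >= before

    def test_gradient_matches_finite_differences(self):
        from seedcascade.experiments import guided_gradient_check

        res = guided_gradient_check(0)
        assert res["max_rel_error"] < 1e-4

    def test_class_index_bounds(self, planted_model):
        with pytest.raises(InvalidArgumentError):
            guided_identity_spectrum(planted_model, 5, GuidedConfig(iterations=1))

    def test_deterministic_given_seed(self, planted_model):
        cfg = GuidedConfig(learning_rate=0.05, iterations=50, rng_seed=4)
        a = guided_identity_spectrum(planted_model, 1, cfg)
        b = guided_identity_spectrum(planted_model, 1, cfg)
        assert np.array_equal(a.x, b.x)


class TestPeaksToBands:
    def test_single_spike(self):
        x = np.zeros(12)
        x[7] = 3.0
        assert peaks_to_bands(x).tolist() == [7]

    def test_two_equal_separated_spikes(self):
        x = np.zeros(12)
        x[2] = x[9] = 1.0
        assert peaks_to_bands(x).tolist() == [2, 9]

    def test_planted_peaks_over_noise_floor(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 0.05, size=20)
        planted = [1, 5, 9, 13, 18]
        for p in planted:
            x[p] = 1.0 + 0.1 * rng.uniform()
        # brute-force enumeration of qualifying local maxima
        found = peaks_to_bands(x, rel_threshold=0.2, min_separation=2)
        assert found.tolist() == planted

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        assert np.array_equal(peaks_to_bands(x), peaks_to_bands(x * 37.5))

    def test_all_zero_empty(self):
        assert peaks_to_bands(np.zeros(10)).size == 0

    def test_min_separation_enforced(self):
        x = np.array([0.0, 0.9, 1.0, 0.9, 0.0, 0.0, 0.8, 0.0])
        out = peaks_to_bands(x, min_separation=3)
        assert out.tolist() == [2, 6]


class TestGuidedSelect:
    def test_per_class_peaks_match_direct_runs(self, planted_model):
        cfg = GuidedConfig(learning_rate=0.05, iterations=200, sparsity_weight=0.3, rng_seed=7)
        res = guided_select(planted_model, "gm:v", cfg)
        rng = np.random.default_rng(7)
        x0 = rng.uniform(0, 1, size=24)
        direct = guided_identity_spectrum(planted_model, 0, cfg, x0=x0)
        assert np.array_equal(
            res.per_class_peaks[planted_model.class_names[0]],
            peaks_to_bands(direct),
        )

    def test_union_of_disjoint_sets_sums_sizes(self):
        axis = make_band_axis("thz", 20, 0.3, 2.0)
        a = SelectionResult("guided", "t", np.array([1, 5]), axis,
                            per_class_peaks={"a": np.array([1, 5]), "b": np.array([10, 15])})
        union = sorted(set(a.per_class_peaks["a"]) | set(a.per_class_peaks["b"]))
        assert len(union) == 4


class TestSPA:
    def test_orthogonal_columns_all_selected(self):
        X = np.array(
            [[2.0, 0.0, 0.0], [0.0, 3.0, 0.0], [0.0, 0.0, 1.5], [0.0, 0.0, 0.0]]
        )
        for start in range(3):
            chain = spa_chain(X, start, 3)
            assert set(chain.tolist()) == {0, 1, 2}

    def test_chain_start_is_first(self):
        X = np.random.default_rng(8).normal(size=(6, 4))
        assert spa_chain(X, 2, 3)[0] == 2

    def test_duplicate_column_never_selected_twice(self):
        rng = np.random.default_rng(9)
        col = rng.normal(size=8)
        X = np.column_stack([col, col, rng.normal(size=8)])
        chain = spa_chain(X, 0, 3)
        assert 1 not in chain  # exact duplicate of the start column

    def test_chain_matches_explicit_gram_schmidt(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            X = rng.normal(size=(8, 5))
            start = int(rng.integers(5))
            chain = spa_chain(X, start, 5)
            # reference: explicit Gram-Schmidt on centered columns
            Xc = X - X.mean(axis=0)
            ref = [start]
            basis = []
            for _ in range(4):
                v = Xc[:, ref[-1]].copy()
                for b in basis:
                    v -= (v @ b) * b
                if np.linalg.norm(v) > 1e-12:
                    basis.append(v / np.linalg.norm(v))
                norms = []
                for j in range(5):
                    r = Xc[:, j].copy()
                    for b in basis:
                        r -= (r @ b) * b
                    norms.append(np.linalg.norm(r) if j not in ref else -1.0)
                ref.append(int(np.argmax(norms)))
            assert chain.tolist() == ref

    def test_k_equal_one_returns_start(self, planted_binary):
        sset, _ = planted_binary
        res = spa_select(
            sset, sset.gm_labels, max_k=1,
            evaluator=lambda X, y: float(np.linalg.norm(X)), rng_seed=0,
        )
        # with k = 1 the best subset is a single band; chain = its start
        assert res.band_indices.size == 1

    def test_selects_discriminative_bands(self, planted_binary):
        sset, planted = planted_binary
        res = spa_select(sset, sset.gm_labels, max_k=4, rng_seed=0, task="gm:v")
        assert res.score == 1.0
        assert set(res.band_indices) <= set(planted.tolist())

    def test_max_k_bound(self, planted_binary):
        sset, _ = planted_binary
        with pytest.raises(InvalidArgumentError):
            spa_select(sset, sset.gm_labels, max_k=0)


class TestSelectionOverlap:
    def _result(self, indices, axis):
        return SelectionResult("spa", "t", np.array(indices, dtype=int), axis)

    def test_identical_sets_full_coverage(self):
        axis = make_band_axis("thz", 20, 0.3, 2.0)
        a = self._result([1, 5, 9], axis)
        rep = selection_overlap(a, self._result([1, 5, 9], axis))
        assert rep["coverage_a_by_b"] == rep["coverage_b_by_a"] == 1.0

    def test_disjoint_sets_zero_at_tolerance_zero(self):
        axis = make_band_axis("thz", 20, 0.3, 2.0)
        rep = selection_overlap(
            self._result([1, 5], axis), self._result([10, 15], axis), tolerance_index=0
        )
        assert rep["coverage_a_by_b"] == 0.0

    def test_tolerance_one_merges_neighbors(self):
        axis = make_band_axis("thz", 20, 0.3, 2.0)
        rep = selection_overlap(
            self._result([4], axis), self._result([5], axis), tolerance_index=1
        )
        assert rep["n_common"] == 1

    def test_mismatched_axes_rejected(self):
        a = self._result([1], make_band_axis("thz", 20, 0.3, 2.0))
        b = self._result([1], make_band_axis("nir", 20, 900, 1700))
        with pytest.raises(InvalidArgumentError):
            selection_overlap(a, b)
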