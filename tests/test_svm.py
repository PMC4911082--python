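"""RBF-SVM training, distance-to-hyperplane scoring, LOO CV and grid search."""

import math

import numpy as np
import pytest

import pepticlass as pc
from pepticlass.errors import ScoringError, TrainingError, ValidationError

from oracles import svm_decision, svm_dual_qp


class TestLogTransform:
    def test_zero_maps_to_zero(self):
        assert pc.log_transform(np.array([0.0]))[0] == 0.0

    def test_closed_form(self):
        assert pc.log_transform(np.array([math.e - 1]))[0] == pytest.approx(1.0)

    def test_monotone(self):
        a = np.array([0.0, 0.5, 1.0, 10.0, 1e6])
        assert np.all(np.diff(pc.log_transform(a)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            pc.log_transform(np.array([-0.1]))


class TestRbfKernel:
    def test_self_similarity_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert pc.rbf_kernel(x, x, gamma=0.5) == 1.0

    def test_gamma_to_zero_limit(self):
        u, v = np.array([0.0, 0.0]), np.array([100.0, 50.0])
        assert pc.rbf_kernel(u, v, gamma=1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_hand_value(self):
        u, v = np.array([0.0, 0.0]), np.array([3.0, 4.0])
        assert pc.rbf_kernel(u, v, gamma=0.04) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            pc.rbf_kernel(np.array([1.0]), np.array([1.0, 2.0]), 0.1)


def _two_point_model(C=10.0, gamma=0.5):
    X = np.array([[0.0, 0.0], [2.0, 0.0]])
    y = np.array([-1, 1])
    return X, y, pc.train(X, y, pc.ClassifierConfig(C=C, gamma=gamma))


class TestTrainAndScore:
    def test_two_point_symmetric_scores(self):
        X, y, model = _two_point_model()
        s0, s1 = model.scores(X)
        assert s0 == pytest.approx(-s1, abs=1e-8)
        assert s1 > 0
        # both points are support vectors on the margin: |score| = 1/||w||
        assert abs(s1) == pytest.approx(1.0 / model.weight_norm, rel=1e-6)

    def test_midpoint_scores_zero(self):
        X, y, model = _two_point_model()
        assert model.score(np.array([1.0, 0.0])) == pytest.approx(0.0, abs=1e-8)

    def test_dual_coefficients_bounded_by_C(self):
        X, y, model = _two_point_model(C=3.0)
        assert np.all(np.abs(model.dual_coef) <= 3.0 + 1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            pc.train(np.zeros((3, 2)), np.ones(3), pc.ClassifierConfig())

    def test_duplicated_dataset_same_boundary(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(3, 1, (10, 3))])
        y = np.array([-1] * 10 + [1] * 10)
        cfg = pc.ClassifierConfig(C=10.0, gamma=0.1)
        m1 = pc.train(X, y, cfg)
        m2 = pc.train(np.vstack([X, X]), np.concatenate([y, y]), cfg)
        probe = rng.normal(1.5, 1.5, (20, 3))
        np.testing.assert_allclose(np.sign(m1.scores(probe)), np.sign(m2.scores(probe)))

    def test_separable_panel_trains_to_perfection(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (15, 4)), rng.normal(4, 0.3, (15, 4))])
        y = np.array([-1] * 15 + [1] * 15)
        model = pc.train(X, y, pc.ClassifierConfig(C=10.0, gamma=0.05))
        assert np.all(np.sign(model.scores(X)) == y)

    def test_removing_non_support_vector_leaves_scores(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.5, (12, 2)), rng.normal(5, 0.5, (12, 2))])
        y = np.array([-1] * 12 + [1] * 12)
        cfg = pc.ClassifierConfig(C=5.0, gamma=0.2)
        model = pc.train(X, y, cfg)
        sv_set = {tuple(v) for v in model.support_vectors}
        keep = np.array([i for i in range(24) if tuple(X[i]) not in sv_set])
        assert keep.size < 24
        drop_one = np.delete(np.arange(24), keep[0])
        m2 = pc.train(X[drop_one], y[drop_one], cfg)
        probe = rng.normal(2.5, 2, (10, 2))
        np.testing.assert_allclose(m2.scores(probe), model.scores(probe), atol=1e-6)

    def test_training_order_invariance(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(2.5, 1, (10, 3))])
        y = np.array([-1] * 10 + [1] * 10)
        cfg = pc.ClassifierConfig(C=2.0, gamma=0.1)
        perm = rng.permutation(20)
        m1 = pc.train(X, y, cfg)
        m2 = pc.train(X[perm], y[perm], cfg)
        probe = rng.normal(1, 2, (10, 3))
        np.testing.assert_allclose(m1.scores(probe), m2.scores(probe), atol=1e-7)

    def test_serialization_bit_stable(self, tmp_path):
        X, y, model = _two_point_model()
        model.to_json(tmp_path / "m.json")
        back = pc.ClassifierModel.from_json(tmp_path / "m.json")
        probe = np.array([[0.3, -0.2], [1.7, 0.4]])
        np.testing.assert_array_equal(back.scores(probe), model.scores(probe))

    def test_missing_panel_peptide_is_scoring_error(self, preprocessed_matrix):
        mat, _ = preprocessed_matrix
        panel = pc.PanelDefinition(name="bad", peptide_ids=[999_999])
        with pytest.raises(ScoringError):
            pc.panel_log_matrix(mat, panel)

    def test_decision_sign_matches_reference_qp(self):
        # libsvm vs generic SLSQP dual solve on small random instances
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(6, 14))
            d = int(rng.integers(2, 5))
            sep = rng.uniform(1.0, 3.0)
            X = rng.normal(0, 1, (n, d))
            y = np.where(rng.random(n) < 0.5, 1, -1)
            X[y > 0] += sep
            C = float(rng.choice([0.5, 1.0, 6.4, 12.8]))
            gamma = float(rng.choice([0.01, 0.1, 0.5]))
            model = pc.train(X, y, pc.ClassifierConfig(C=C, gamma=gamma))
            alpha, bias = svm_dual_qp(X, y, C, gamma)
            probe = rng.normal(sep / 2, 2.0, (8, d))
            ref = svm_decision(X, y, alpha, bias, gamma, probe)
            mine = model.decision_value(probe)
            mask = np.abs(ref) > 0.05  # skip near-boundary probes
            assert np.all(np.sign(mine[mask]) == np.sign(ref[mask]))


class TestLooAndGrid:
    def _separated(self, n1=8, n2=8, seed=5):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 0.4, (n1, 3)), rng.normal(4, 0.4, (n2, 3))])
        y = np.array([-1] * n1 + [1] * n2)
        return X, y

    def test_loo_perfect_on_separated_data(self):
        X, y = self._separated()
        _, sens, spec = pc.loo_cross_validate(X, y, pc.ClassifierConfig(C=10, gamma=0.1))
        assert sens == 1.0 and spec == 1.0

    def test_loo_identical_copies_classify_correctly(self):
        X = np.array([[0.0, 0.0]] * 5 + [[3.0, 3.0]] * 5)
        y = np.array([-1] * 5 + [1] * 5)
        scores, sens, spec = pc.loo_cross_validate(X, y, pc.ClassifierConfig(C=5, gamma=0.3))
        assert sens == 1.0 and spec == 1.0

    def test_loo_refuses_tiny_n(self):
        with pytest.raises(TrainingError):
            pc.loo_cross_validate(np.zeros((3, 2)), np.array([1, -1, 1]),
                                  pc.ClassifierConfig())

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(8)
        accs = []
        for seed in range(10):
            X, _ = self._separated(10, 10, seed=seed)
            y = rng.permutation(np.array([-1] * 10 + [1] * 10))
            scores, sens, spec = pc.loo_cross_validate(
                X, y, pc.ClassifierConfig(C=1.0, gamma=0.1))
            accs.append(0.5 * (sens + spec))
        assert 0.25 < np.mean(accs) < 0.75

    def test_grid_single_point_returned(self):
        X, y = self._separated()
        cfg, table = pc.grid_search(X, y, [2.0], [0.05])
        assert cfg.C == 2.0 and cfg.gamma == 0.05
        assert len(table) == 1

    def test_grid_prefers_working_configuration(self):
        X, y = self._separated()
        cfg, table = pc.grid_search(X, y, [0.01, 6.4], [0.001024])
        best = max(t["balanced_accuracy"] for t in table)
        chosen = [t for t in table if t["C"] == cfg.C and t["gamma"] == cfg.gamma][0]
        assert chosen["balanced_accuracy"] == best == 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            pc.grid_search(np.zeros((4, 2)), np.array([1, -1, 1, -1]), [], [1.0])
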