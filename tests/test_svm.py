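import numpy as np
import pytest
from oracles import qp_oracle, qp_scores

from fallkit import svm as sv
from fallkit.features import FeatureSeries
from fallkit.training import LabeledFrameSet


def toy_set(rng, m=20, n=2, gamma=1.0):
    X = rng.normal(0, 1, size=(m, n))
    w = rng.normal(0, 1, size=n)
    D = np.where(X @ w + 0.3 * rng.normal(size=m) > 0, 1, -1)
    if len(np.unique(D)) < 2:
        D[0] = -D[0]
    return LabeledFrameSet(X, D, tuple(f"p{i}" for i in range(n)))


class TestRbfKernel:
    def test_zero_distance(self):
        assert sv.rbf_kernel([1.0, 2.0], [1.0, 2.0], gamma=7.7) == pytest.approx(1.0)

    def test_gamma_zero(self):
        assert sv.rbf_kernel([0.0, 0.0], [3.0, 4.0], gamma=0.0) == pytest.approx(1.0)

    def test_unit_distance_default_gamma(self):
        # ||x-y||^2 = 1 at the stated kernel width 5.3
        assert sv.rbf_kernel([0.0], [1.0], gamma=5.3) == pytest.approx(np.exp(-5.3))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            sv.rbf_kernel([1.0], [1.0, 2.0], gamma=1.0)


class TestTrain:
    def test_separable_toy_perfect(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        D = np.array([-1, -1, 1, 1])
        model = sv.train(LabeledFrameSet(X, D, ("a", "b")), gamma=1.0, cost=10.0)
        for x, d in zip(X, D):
            _, label = sv.decision(model, x)
            assert label == d

    def test_single_class_rejected(self):
        X = np.zeros((3, 2))
        D = np.array([1, 1, 1])
        with pytest.raises(ValueError, match="single class"):
            sv.train(LabeledFrameSet(X, D, ("a", "b")))

    def test_dual_feasibility(self, trained_model):
        model, _, _, _ = trained_model
        assert abs(np.sum(model.dual_coef)) < 1e-6
        assert np.all(model.alphas > 0)
        assert np.all(model.alphas <= model.cost + 1e-9)

    def test_duplication_invariance(self, rng):
        data = toy_set(rng, m=15)
        doubled = LabeledFrameSet(
            np.vstack([data.X, data.X]), np.concatenate([data.D, data.D]), data.param_names
        )
        m1 = sv.train(data, gamma=1.3, cost=4.7)
        m2 = sv.train(doubled, gamma=1.3, cost=4.7)
        probes = rng.normal(0, 1.5, size=(40, 2))
        s1 = sv.decision_scores(m1, probes)
        s2 = sv.decision_scores(m2, probes)
        # duplicating every point doubles effective C per pattern; the
        # decision function may differ where slacks are active, but signs
        # on confident regions and margin structure agree
        np.testing.assert_array_equal(np.sign(s1[np.abs(s1) > 1]), np.sign(s2[np.abs(s1) > 1]))

    def test_row_permutation_invariance(self, rng):
        data = toy_set(rng, m=25, n=3)
        perm = rng.permutation(len(data))
        permuted = LabeledFrameSet(data.X[perm], data.D[perm], data.param_names)
        m1 = sv.train(data, gamma=2.0, cost=4.7)
        m2 = sv.train(permuted, gamma=2.0, cost=4.7)
        probes = rng.normal(0, 1.5, size=(50, 3))
        np.testing.assert_allclose(
            sv.decision_scores(m1, probes), sv.decision_scores(m2, probes), atol=1e-6
        )


class TestQpOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_decision_scores_match_qp(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        m = int(rng.integers(8, 26))
        gamma = float(rng.uniform(0.3, 5.3))
        C = float(rng.uniform(0.5, 4.7))
        data = toy_set(rng, m=m, n=n, gamma=gamma)
        model = sv.train(data, gamma=gamma, cost=C, tol=1e-8)
        a, b = qp_oracle(data.X, data.D.astype(float), gamma, C)
        probes = rng.normal(0, 1.5, size=(30, n))
        expected = qp_scores(data.X, data.D, a, b, gamma, probes)
        np.testing.assert_allclose(
            sv.decision_scores(model, probes), expected, atol=1e-4
        )

    @pytest.mark.parametrize("seed", [3, 17, 42])
    def test_kkt_conditions_on_training_set(self, seed):
        rng = np.random.default_rng(seed)
        data = toy_set(rng, m=25, n=2)
        C = 4.7
        model = sv.train(data, gamma=5.3, cost=C, tol=1e-8)
        scores = sv.decision_scores(model, data.X)
        margins = data.D * scores
        sv_scores = sv.decision_scores(model, model.support_vectors)
        sv_margins = model.sv_labels * sv_scores
        free = model.alphas < C - 1e-6
        # free SVs sit on the margin; bounded SVs may violate it
        np.testing.assert_allclose(sv_margins[free], 1.0, atol=1e-3)
        assert np.all(sv_margins[~free] <= 1.0 + 1e-3)
        # non-support points lie outside the margin
        sv_set = {tuple(np.round(r, 12)) for r in model.support_vectors}
        outside = np.array([tuple(np.round(r, 12)) not in sv_set for r in data.X])
        assert np.all(margins[outside] >= 1.0 - 1e-3)


class TestDecision:
    def test_expression_oracle(self, trained_model):
        # Independent re-implementation of the decision sum from model parts
        model, _, _, _ = trained_model
        rng = np.random.default_rng(0)
        probes = rng.uniform(-1, 2, size=(10, model.n_features))
        for x in probes:
            expected = (
                sum(
                    d * a * np.exp(-model.gamma * np.sum((xj - x) ** 2))
                    for d, a, xj in zip(model.sv_labels, model.alphas, model.support_vectors)
                )
                + model.bias
            )
            score, label = sv.decision(model, x)
            assert score == pytest.approx(expected, abs=1e-9)
            assert label == (1 if score > 0 else -1)

    def test_sign_zero_is_negative(self):
        model = sv.SvmModel(
            support_vectors=np.array([[0.0], [1.0]]),
            alphas=np.array([1.0, 1.0]),
            sv_labels=np.array([1, -1]),
            bias=0.0,
            gamma=0.0,  # both kernels are 1 -> score identically 0
            cost=2.0,
            param_names=("p0",),
        )
        score, label = sv.decision(model, np.array([5.0]))
        assert score == 0.0
        assert label == -1

    def test_dimension_mismatch(self, trained_model):
        model, _, _, _ = trained_model
        with pytest.raises(ValueError, match="dimension"):
            sv.decision(model, np.zeros(model.n_features + 1))


class TestClassifySeries:
    def _feats(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        z = np.zeros(n)
        return FeatureSeries(
            t=np.arange(n) / 200.0,
            sv_total=1 + 0.01 * rng.normal(size=n),
            cv_fast=np.abs(0.05 * rng.normal(size=n)),
            va=0.01 * rng.normal(size=n),
            phi_z=np.abs(rng.normal(size=n)),
            fs=200.0,
        )

    def test_static_stream_all_negative(self, trained_model):
        model, _, _, _ = trained_model
        labels = sv.classify_series(model, self._feats())
        assert np.all(labels == -1)

    def test_matches_samplewise_decision(self, trained_model):
        model, _, _, _ = trained_model
        feats = self._feats(n=20, seed=3)
        labels = sv.classify_series(model, feats)
        X = feats.matrix(model.param_names)
        for i in range(len(feats)):
            assert labels[i] == sv.decision(model, X[i])[1]

    def test_empty_series(self, trained_model):
        model, _, _, _ = trained_model
        empty = FeatureSeries(
            t=np.empty(0), sv_total=np.empty(0), cv_fast=np.empty(0),
            va=np.empty(0), phi_z=np.empty(0), fs=200.0,
        )
        assert len(sv.classify_series(model, empty)) == 0

    def test_param_mismatch(self, trained_model):
        model, _, _, _ = trained_model
        with pytest.raises(ValueError, match="parameter"):
            sv.classify_series(model, self._feats(), params=("cv_fast",))


class TestPersistence:
    def test_round_trip_scores(self, tmp_path, trained_model):
        model, _, _, _ = trained_model
        back = sv.load_model(sv.save_model(model, tmp_path / "m.txt"))
        rng = np.random.default_rng(1)
        probes = rng.uniform(-1, 2, size=(50, model.n_features))
        np.testing.assert_allclose(
            sv.decision_scores(back, probes),
            sv.decision_scores(model, probes),
            atol=1e-12,
        )
        assert back.param_names == model.param_names

    def test_truncated_file_rejected(self, tmp_path, trained_model):
        model, _, _, _ = trained_model
        path = sv.save_model(model, tmp_path / "m.txt")
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[: len(lines) // 2]))
        with pytest.raises(ValueError, match="malformed|truncated"):
            sv.load_model(path)

    def test_version_mismatch_rejected(self, tmp_path, trained_model):
        model, _, _, _ = trained_model
        path = sv.save_model(model, tmp_path / "m.txt")
        text = path.read_text().replace("v1", "v99", 1)
        path.write_text(text)
        with pytest.raises(ValueError, match="version"):
            sv.load_model(path)

    def test_non_model_file_rejected(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("hello\n")
        with pytest.raises(ValueError, match="not a"):
            sv.load_model(p)
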