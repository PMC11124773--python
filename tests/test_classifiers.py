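"""Linear SVM + Platt scaling, the SCG MLP, and the boosting ensemble."""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from swallowsound.classifiers import (
    EnsembleModel,
    LinearSvmModel,
    PlattCalibration,
    TrainingSet,
    fit_platt,
    predict,
    svm_primal_objective,
    train_ensemble,
    train_linear_svm,
    train_mlp,
)


def qp_oracle_objective(x, y_signed, c):
    """Generic convex-solver solution of the primal soft-margin QP."""
    n, d = x.shape
    cn = np.full(n, c)

    def obj(z):
        return 0.5 * z[:d] @ z[:d] + cn @ z[d + 1 :]

    def grad(z):
        g = np.zeros_like(z)
        g[:d] = z[:d]
        g[d + 1 :] = cn
        return g

    a = np.zeros((n, d + 1 + n))
    a[:, :d] = y_signed[:, None] * x
    a[:, d] = y_signed
    a[:, d + 1 :] = np.eye(n)
    res = minimize(
        obj,
        np.concatenate([np.zeros(d + 1), np.ones(n)]),
        jac=grad,
        method="SLSQP",
        constraints=[LinearConstraint(a, lb=1.0, ub=np.inf)],
        bounds=[(None, None)] * (d + 1) + [(0, None)] * n,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    return res.fun


def random_svm_instances(n_instances, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(10, 31))
        d = int(rng.integers(2, 6))
        x = rng.standard_normal((n, d))
        y_signed = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        if len(np.unique(y_signed)) < 2:
            y_signed[0] = -y_signed[0]
        c = float(rng.choice([0.05, 0.5, 2.0]))
        yield x, y_signed, c


class TestTrainingSet:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            TrainingSet(np.zeros((4, 2)), np.zeros(4))

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            TrainingSet(np.zeros((3, 2)), np.array([0, 1, 2]))


class TestLinearSvm:
    def test_canonical_max_margin(self):
        x = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        model = train_linear_svm(x, y, c=1000.0)
        assert model.w[0] == pytest.approx(1.0, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)

    def test_contradictory_labels_use_slack(self):
        x = np.array([[0.0], [0.0], [1.0], [-1.0]])
        y = np.array([1, 0, 1, 0])
        model = train_linear_svm(x, y, c=1.0)
        assert np.max(model.slack) > 0

    def test_objective_matches_qp_oracle(self):
        for x, y_signed, c in random_svm_instances(20, seed=0):
            model = train_linear_svm(x, (y_signed > 0).astype(int), c=c)
            impl = svm_primal_objective(model.w, model.b, x, y_signed, c)
            oracle = qp_oracle_objective(x, y_signed, c)
            assert impl == pytest.approx(oracle, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.zeros((4, 2)), np.ones(4))


class TestPlatt:
    def test_sigmoid_midpoint(self):
        cal = PlattCalibration(a=-1.0, b=0.0)
        assert cal.probability(np.array([0.0]))[0] == pytest.approx(0.5)

    def test_limit_behaviour(self):
        cal = PlattCalibration(a=-1.0, b=0.0)
        assert cal.probability(np.array([50.0]))[0] == pytest.approx(1.0, abs=1e-12)
        assert cal.probability(np.array([-50.0]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        a_true, b_true = -2.0, 0.5
        scores = rng.normal(0.25, 1.5, size=5000)
        probs = 1.0 / (1.0 + np.exp(a_true * scores + b_true))
        labels = (rng.random(5000) < probs).astype(int)
        cal = fit_platt(scores, labels)
        assert cal.a == pytest.approx(a_true, rel=0.10)
        assert cal.b == pytest.approx(b_true, rel=0.10)

    def test_probabilities_monotone_in_score(self):
        rng = np.random.default_rng(12)
        scores = rng.standard_normal(200)
        labels = (scores + 0.3 * rng.standard_normal(200) > 0).astype(int)
        cal = fit_platt(scores, labels)
        grid = np.linspace(-4, 4, 100)
        assert np.all(np.diff(cal.probability(grid)) > 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_platt(np.arange(5.0), np.ones(5))


class TestMlp:
    def test_hidden_layer_size_rule(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((30, 60))
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        model = train_mlp(x, y, max_epochs=5)
        assert model.hidden_size == 62

    def test_learns_xor(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        solved = False
        for seed in range(5):
            model = train_mlp(x, y, max_epochs=2000, seed=seed)
            if np.all(predict(model, x).predicted_class == y):
                solved = True
                break
        assert solved, "no seed reached 100% training accuracy on XOR"

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((40, 6))
        y = (x[:, 0] > 0).astype(int)
        m1 = train_mlp(x, y, max_epochs=100, seed=3)
        m2 = train_mlp(x, y, max_epochs=100, seed=3)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)
        assert m1.epochs_run == m2.epochs_run

    def test_output_is_probability(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal((50, 4))
        y = (x[:, 0] + x[:, 1] > 0).astype(int)
        model = train_mlp(x, y, max_epochs=200, seed=0)
        p = model.class1_probability(x)
        assert np.all((p >= 0) & (p <= 1))


def _stub_svm(direction, platt_a=-4.0):
    """A hand-built 1-D SVM voting +1 when direction * x > 0."""
    return LinearSvmModel(
        w=np.array([direction]),
        b=0.0,
        c=0.05,
        slack=np.zeros(1),
        platt=PlattCalibration(a=platt_a, b=0.0),
    )


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(16)
    x = np.vstack([rng.normal(-2, 1, (40, 3)), rng.normal(2, 1, (40, 3))])
    y = np.repeat([0, 1], 40)
    return x, y


class TestEnsemble:

    def test_ten_learners_by_default(self, separable_data):
        x, y = separable_data
        model = train_ensemble(x, y, mlp_max_epochs=200, seed=0)
        assert len(model.learners) == 10
        svm_count = sum(isinstance(m, LinearSvmModel) for m in model.learners)
        assert svm_count == 5

    def test_alternating_order(self, separable_data):
        x, y = separable_data
        model = train_ensemble(x, y, mlp_max_epochs=200, seed=0)
        kinds = [type(m).__name__ for m in model.learners]
        assert kinds[:4] == ["LinearSvmModel", "MlpModel", "LinearSvmModel", "MlpModel"]

    def test_round_errors_below_half(self, separable_data):
        x, y = separable_data
        model = train_ensemble(x, y, mlp_max_epochs=200, seed=0)
        assert np.all(model.round_errors < 0.5)
        assert np.all(model.round_errors >= 0.0)

    def test_training_error_nonincreasing_over_rounds(self, separable_data):
        x, y = separable_data
        model = train_ensemble(x, y, mlp_max_epochs=200, seed=0)
        votes = np.stack(
            [np.where(predict(m, x).probability > 0.5, 1.0, -1.0) for m in model.learners]
        )
        y_signed = np.where(y == 1, 1.0, -1.0)
        errors = []
        for t in range(1, len(model.learners) + 1):
            combined = np.sign(model.alphas[:t] @ votes[:t])
            errors.append(np.mean(np.where(combined > 0, 1, 0) != y))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_hand_computed_weighted_vote(self):
        learners = (_stub_svm(1.0), _stub_svm(-1.0), _stub_svm(-1.0))
        model = EnsembleModel(
            learners=learners,
            alphas=np.array([0.5, 0.3, 0.1]),
            round_errors=np.zeros(3),
        )
        # at x = +1 the votes are (+1, -1, -1): 0.5 > 0.4 -> class 1
        result = predict(model, np.array([1.0]))
        assert result.predicted_class == 1
        assert result.probability == pytest.approx(0.5 / 0.9)
        assert result.score == pytest.approx(0.1)

    def test_unanimous_vote(self):
        model = EnsembleModel(
            learners=tuple(_stub_svm(1.0) for _ in range(10)),
            alphas=np.full(10, 0.7),
            round_errors=np.zeros(10),
        )
        result = predict(model, np.array([2.0]))
        assert result.predicted_class == 1
        assert result.probability == pytest.approx(1.0)

    def test_exact_tie_goes_to_class_zero(self):
        model = EnsembleModel(
            learners=(_stub_svm(1.0), _stub_svm(-1.0)),
            alphas=np.array([0.5, 0.5]),
            round_errors=np.zeros(2),
        )
        assert predict(model, np.array([1.0])).predicted_class == 0

    def test_singleton_ensemble_equals_learner(self, separable_data):
        x, y = separable_data
        model = train_ensemble(x, y, n_svm=1, n_mlp=0, seed=0)
        assert len(model.learners) == 1
        single = model.learners[0]
        np.testing.assert_array_equal(
            predict(model, x).predicted_class, predict(single, x).predicted_class
        )

    def test_identical_learners_reproduce_single_decision(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal((30, 1))
        base = _stub_svm(1.0)
        model = EnsembleModel(
            learners=(base, base, base),
            alphas=np.array([0.9, 0.2, 0.4]),
            round_errors=np.zeros(3),
        )
        np.testing.assert_array_equal(
            predict(model, x).predicted_class, predict(base, x).predicted_class
        )

    def test_dimension_mismatch_rejected(self, separable_data):
        x, y = separable_data
        model = train_ensemble(x, y, n_svm=1, n_mlp=0, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros(7))


class TestStandardizationInvariance:
    def test_svm_predictions_invariant_to_coordinate_rescaling(self):
        """z-scoring composed with SVM training absorbs affine feature scaling."""
        from swallowsound.evaluation import Standardizer

        rng = np.random.default_rng(18)
        x = rng.standard_normal((60, 4))
        y = (x[:, 0] - 0.5 * x[:, 2] > 0).astype(int)
        x_test = rng.standard_normal((20, 4))

        scaled = x.copy()
        scaled[:, 1] = 50.0 * scaled[:, 1] - 3.0
        scaled_test = x_test.copy()
        scaled_test[:, 1] = 50.0 * scaled_test[:, 1] - 3.0

        def fit_predict(train, test):
            sc = Standardizer.fit(train)
            model = train_linear_svm(sc.transform(train), y, c=0.05)
            return predict(model, sc.transform(test)).predicted_class

        np.testing.assert_array_equal(
            fit_predict(x, x_test), fit_predict(scaled, scaled_test)
        )
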