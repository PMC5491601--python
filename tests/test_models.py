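"""Linear / MLP / RBF fits, predictions, reports and serialization."""

import numpy as np
import pytest

from rumenzeta.errors import FitError, PredictionError
from rumenzeta.models import (
    LinearModel,
    Preprocessing,
    RBFModel,
    fit_linear,
    fit_mlp,
    fit_rbf,
    fit_report,
    load_model,
    model_from_dict,
    model_to_dict,
    predict,
    save_model,
    select_best_model,
)


class TestLinear:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        model = fit_linear((x, 1.0 + 2.0 * x))
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert model.coef[0] == pytest.approx(2.0, abs=1e-10)
        assert predict(model, np.array([3.0])) == pytest.approx([7.0])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, p = 50, 3
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            model = fit_linear((X, y))
            A = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.allclose(
                np.r_[model.intercept, model.coef], beta, rtol=1e-8
            )

    def test_matches_sklearn_cross_check(self):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + rng.normal(0, 0.1, 80)
        ours = fit_linear((X, y))
        ref = sklearn_linear.LinearRegression().fit(X, y)
        assert np.allclose(ours.coef, ref.coef_, rtol=1e-8)
        assert ours.intercept == pytest.approx(ref.intercept_, rel=1e-8)

    def test_training_residual_mean_zero(self, small_dataset):
        model = fit_linear(small_dataset)
        err = small_dataset.y - predict(model, small_dataset)
        assert abs(err.mean()) < 1e-9

    def test_n_not_greater_than_p_rejected(self):
        X = np.eye(3)
        with pytest.raises(FitError):
            fit_linear((X, np.ones(3)))

    def test_rank_deficient_design_solved_minimum_norm(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        X = np.column_stack([x, x])  # duplicated feature
        model = fit_linear((X, 3.0 * x))
        assert model.rank < 3
        assert np.allclose(predict(model, X), 3.0 * x, atol=1e-8)


class TestMLP:
    def test_learns_quadratic(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 200)
        model = fit_mlp((x, x**2), hidden=5, seed=1)
        rep = fit_report(model, (x, x**2))
        assert rep.training.correlation >= 0.99

    def test_zero_epochs_returns_seeded_init(self):
        x = np.linspace(-1, 1, 30)
        a = fit_mlp((x, x), hidden=3, epochs_bp=0, epochs_cg=0, seed=9)
        b = fit_mlp((x, x), hidden=3, epochs_bp=0, epochs_cg=0, seed=9)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)
        assert a.loss_trace == ()
        trained = fit_mlp((x, x), hidden=3, seed=9)
        assert not np.array_equal(a.w1, trained.w1)

    def test_seed_determinism_bit_identical(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 100)
        y = np.sin(2 * x)
        a = fit_mlp((x, y), hidden=4, seed=5)
        b = fit_mlp((x, y), hidden=4, seed=5)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.b1, b.b1)
        assert np.array_equal(a.w2, b.w2) and a.b2 == b.b2

    def test_cg_phase_does_not_increase_loss(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 150)
        model = fit_mlp((x, x**2), hidden=5, seed=2)
        cg = [loss for phase, _, loss in model.loss_trace if phase == "cg"]
        assert cg[-1] <= cg[0] + 1e-12

    def test_divergence_reports_learning_rate(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 50)
        with pytest.raises(FitError, match="learning rate"):
            fit_mlp((x, 100 * x), hidden=5, learning_rate=50.0,
                    epochs_cg=0, seed=0)


class TestRBF:
    def test_interpolates_when_centers_equal_cases(self):
        x = np.linspace(0, 1, 25)
        y = np.sin(7 * x)
        model = fit_rbf((x, y), hidden=25, seed=0)
        rep = fit_report(model, (x, y))
        assert rep.training.correlation >= 1 - 1e-6

    def test_beats_linear_on_sine(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 300)
        y = np.sin(4 * x)
        rbf = fit_rbf((x, y), hidden=30, seed=0)
        lin = fit_linear((x, y))
        assert fit_report(rbf, (x, y)).training.correlation >= 0.99
        assert fit_report(lin, (x, y)).training.correlation < 0.5

    def test_output_layer_is_exact_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 2))
        y = rng.normal(size=120)
        model = fit_rbf((X, y), hidden=15, seed=0)
        phi = model._activations(model.preprocessing.transform(X))
        A = np.column_stack([phi, np.ones(len(X))])
        resid = y - A @ np.r_[model.weights, model.bias]
        # residual orthogonal to the design columns
        assert np.max(np.abs(A.T @ resid)) <= 1e-8 * max(1.0, np.abs(y).sum())

    def test_widths_positive(self, small_dataset):
        model = fit_rbf(small_dataset, hidden=40, seed=0)
        assert np.all(model.widths > 0)

    def test_more_hidden_units_than_cases_rejected(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(FitError):
            fit_rbf((x, x), hidden=11, seed=0)

    def test_seed_determinism(self, small_dataset):
        a = fit_rbf(small_dataset, hidden=30, seed=4)
        b = fit_rbf(small_dataset, hidden=30, seed=4)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.weights, b.weights)

    def test_kmeans_matches_sklearn_inertia(self):
        cluster = pytest.importorskip("sklearn.cluster")
        from rumenzeta.models import _kmeans

        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(loc, 0.1, size=(50, 2))
            for loc in ((0, 0), (3, 0), (0, 3))
        ])
        centers = _kmeans(X, 3, np.random.default_rng(1))
        from scipy.spatial.distance import cdist

        ours = cdist(X, centers, "sqeuclidean").min(axis=1).sum()
        ref = cluster.KMeans(3, n_init=10, random_state=0).fit(X).inertia_
        assert ours == pytest.approx(ref, rel=0.05)

    def test_nesting_rbf_at_least_linear_training_correlation(
        self, small_dataset, fixture_dataset
    ):
        for ds, hidden in ((small_dataset, 150), (fixture_dataset, 120)):
            lin = fit_linear(ds)
            rbf = fit_rbf(ds, hidden=hidden, seed=0)
            r_lin = fit_report(lin, ds).training.correlation
            r_rbf = fit_report(rbf, ds).training.correlation
            assert r_rbf >= r_lin - 1e-6


class TestPredictAndReport:
    def test_linear_identity_on_em(self):
        model = LinearModel(intercept=0.0, coef=(1.0,), manifest=("zeta_em",))
        assert predict(model, np.array([[0.5]])) == pytest.approx([0.5])

    def test_rbf_unit_response_at_center(self):
        model = RBFModel(
            centers=np.array([[0.3, -0.2]]), widths=np.array([0.7]),
            weights=np.array([1.0]), bias=0.0,
            manifest=("a", "b"), preprocessing=Preprocessing(),
        )
        assert predict(model, np.array([[0.3, -0.2]])) == pytest.approx([1.0])

    def test_manifest_mismatch_names_features(self, small_dataset):
        model = LinearModel(intercept=0.0, coef=(1.0,), manifest=("nope",))
        with pytest.raises(PredictionError, match="nope"):
            predict(model, small_dataset)

    def test_perfect_predictions(self):
        x = np.linspace(0, 1, 20)
        model = fit_linear((x, 2 * x))
        rep = fit_report(model, (x, 2 * x))
        assert rep.training.correlation == pytest.approx(1.0)
        assert rep.training.error_mean == pytest.approx(0.0, abs=1e-12)
        assert rep.training.error_sd == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_error_convention(self):
        # error = observed - predicted
        x = np.linspace(0, 1, 20)
        model = fit_linear((x, 2 * x))
        rep = fit_report(model, (x, 2 * x + 1.0))
        assert rep.training.correlation == pytest.approx(1.0)
        assert rep.training.error_mean == pytest.approx(1.0)

    def test_constant_predictions_flagged_degenerate(self):
        x = np.linspace(0, 1, 20)
        model = LinearModel(intercept=0.5, coef=(0.0,), manifest=("x0",))
        rep = fit_report(model, (x[:, None], x))
        assert rep.training.degenerate
        assert rep.training.correlation == 0.0

    def test_best_model_by_validation_correlation(self, small_dataset):
        from rumenzeta import split_train_validation

        train, val = split_train_validation(small_dataset, seed=0)
        reports = {
            "linear": fit_report(fit_linear(train), train, val),
            "rbf": fit_report(fit_rbf(train, hidden=150, seed=0), train, val),
        }
        assert select_best_model(reports) == "rbf"


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path, small_dataset):
        sub = small_dataset.subset(range(200))
        models = [
            fit_linear(sub),
            fit_mlp(sub, hidden=3, epochs_bp=10, epochs_cg=20, seed=0),
            fit_rbf(sub, hidden=20, seed=0),
        ]
        for i, model in enumerate(models):
            path = tmp_path / f"m{i}.json"
            save_model(model, path)
            back = load_model(path)
            assert np.allclose(predict(back, sub), predict(model, sub),
                               rtol=1e-12, atol=1e-12)

    def test_dict_roundtrip_manifest(self, small_dataset):
        model = fit_linear(small_dataset)
        back = model_from_dict(model_to_dict(model))
        assert back.manifest == model.manifest
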