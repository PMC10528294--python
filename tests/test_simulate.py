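"""Synthetic-data generator: covariances, designs, responses, determinism."""

import numpy as np
import pytest

from dcforest import (
    InvalidConfigurationError,
    InvalidInputError,
    SimulationSetting,
    ar1_covariance,
    dcor_profile,
    draw_design,
    generate,
    response,
    setting2_covariance,
    surface,
)
from dcforest.simulate import MODEL_SIGNAL_FEATURES


class TestCovariances:
    def test_ar1_exact_small_case(self):
        np.testing.assert_allclose(
            ar1_covariance(3, 0.5),
            [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]],
        )

    def test_ar1_rho_zero_is_identity(self):
        np.testing.assert_allclose(ar1_covariance(4, 0.0), np.eye(4))

    def test_ar1_positive_definite_at_large_p(self):
        lam = np.linalg.eigvalsh(ar1_covariance(500, 0.8))
        assert lam[0] > 0

    def test_ar1_rejects_unit_rho(self):
        with pytest.raises(InvalidInputError):
            ar1_covariance(3, 1.0)

    def test_setting2_small_case(self):
        np.testing.assert_allclose(setting2_covariance(2, 0.5), [[1, 0.7], [0.7, 1]])

    def test_setting2_unit_diagonal_and_pd(self):
        sigma = setting2_covariance(500, 0.5)
        np.testing.assert_allclose(np.diag(sigma), 1.0)
        assert np.linalg.eigvalsh(sigma)[0] > 0

    def test_setting2_non_pd_rho_rejected(self):
        with pytest.raises(InvalidConfigurationError, match="eigenvalue"):
            setting2_covariance(200, -0.9)


class TestDesigns:
    def test_normal_design_recovers_covariance(self):
        s = SimulationSetting(model=3, setting=1, p=3, rho=0.5, seed=1)
        X = draw_design(s, 50000)
        emp = np.cov(X, rowvar=False)
        np.testing.assert_allclose(emp, ar1_covariance(3, 0.5), atol=0.02)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=0.02)

    def test_uniform_design_support_and_marginals(self):
        from scipy.stats import kstest

        s = SimulationSetting(model=3, setting=4, p=4, seed=2)
        X = draw_design(s, 10000)
        assert X.min() >= 0.0 and X.max() <= 1.0
        for j in range(4):
            assert kstest(X[:, j], "uniform").pvalue > 0.01

    def test_same_seed_same_design(self):
        s = SimulationSetting(model=1, setting=1, p=6, rho=0.5, seed=9)
        np.testing.assert_array_equal(draw_design(s, 20), draw_design(s, 20))


class TestResponses:
    def test_model1_direct_evaluation(self):
        X = np.zeros((1, 5))
        X[0, :4] = 1.0
        assert surface(1, X)[0] == pytest.approx(8.0)

    def test_model2_direct_evaluation(self):
        X = np.zeros((1, 55))
        X[0, [0, 19, 32, 54]] = [2.0, 3.0, 2.0, 3.0]
        # 2^2 + 3 + 2^3 + 3^2
        assert surface(2, X)[0] == pytest.approx(4 + 3 + 8 + 9)

    def test_model3_hinge_annihilates_below_quarter(self):
        X = np.array([[0.9, 0.2], [0.0, 0.75]])
        np.testing.assert_allclose(surface(3, X), [0.0, 100 * 0.25 * 0.5])

    def test_model1_population_variance(self):
        # Var(y) = c' Sigma c + 1 = 40.25 for c = (5,1,1,1,0,...) at rho=0.5
        c = np.array([5.0, 1.0, 1.0, 1.0, 0.0])
        sigma = ar1_covariance(5, 0.5)
        assert c @ sigma @ c + 1 == pytest.approx(40.25)
        s = SimulationSetting(model=1, setting=1, p=5, rho=0.5, seed=4)
        X = draw_design(s, 100000)
        y = response(1, X, noise_seed=5)
        assert y.var() == pytest.approx(40.25, rel=0.01)

    def test_insufficient_p_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            response(2, np.zeros((5, 10)), noise_seed=0)
        with pytest.raises(InvalidConfigurationError):
            SimulationSetting(model=2, setting=3, p=54, rho=0.8)


class TestGenerate:
    def test_default_split_shapes(self):
        tr, te = generate(SimulationSetting(model=1, setting=1, p=10, rho=0.5, seed=3))
        assert tr.X.shape == (200, 10) and te.X.shape == (1000, 10)
        assert tr.split == "train" and te.split == "test"

    def test_bit_identical_regeneration(self):
        s = SimulationSetting(model=3, setting=4, p=5, seed=12)
        a = generate(s)
        b = generate(s)
        np.testing.assert_array_equal(a[0].X, b[0].X)
        np.testing.assert_array_equal(a[1].y, b[1].y)

    def test_train_test_share_no_rows(self):
        tr, te = generate(SimulationSetting(model=3, setting=4, p=4, seed=8))
        train_rows = {r.tobytes() for r in tr.X}
        assert all(r.tobytes() not in train_rows for r in te.X)

    def test_changing_n_test_keeps_training_draw(self):
        s1 = SimulationSetting(model=1, setting=1, p=6, rho=0.5, n_test=100, seed=5)
        s2 = SimulationSetting(model=1, setting=1, p=6, rho=0.5, n_test=500, seed=5)
        np.testing.assert_array_equal(generate(s1)[0].X, generate(s2)[0].X)

    @pytest.mark.parametrize(
        "model, setting, rho, p",
        [(1, 1, 0.5, 60), (2, 3, 0.8, 60), (3, 4, None, 60)],
    )
    def test_signal_features_outscore_noise_at_large_n(self, model, setting, rho, p):
        s = SimulationSetting(
            model=model, setting=setting, p=p, rho=rho, n_train=1500, n_test=1, seed=21
        )
        tr, _ = generate(s)
        scores = dcor_profile(tr.X, tr.y).scores
        signal = list(MODEL_SIGNAL_FEATURES[model])
        noise = [j for j in range(p) if j not in signal]
        # every signal feature beats every feature not correlated with one;
        # under AR designs, neighbors of signal columns may score in between,
        # so compare against far-away noise only
        far_noise = [j for j in noise if all(abs(j - s_) > 6 for s_ in signal)]
        assert min(scores[signal]) > max(scores[far_noise])
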