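"""Gaussian diagnostic model: moments, pdf, Mahalanobis, classifiers, I/O."""

import numpy as np
import pytest
from scipy.stats import chi2, multivariate_normal

from hipdx.angles import AngleTriplet
from hipdx.errors import DegenerateModelError, InputError, ModelSchemaError
from hipdx.model import (GaussianModel, KnowledgeThresholds, classify_data_driven,
                         classify_knowledge, ellipsoid_axes, fit_gaussian,
                         load_model, mahalanobis_sq, pdf, serialize_model)


def random_spd(rng, scale=5.0):
    a = rng.normal(0, scale, size=(3, 3))
    return a @ a.T + 0.5 * np.eye(3)


@pytest.fixture
def identity_model():
    return GaussianModel(mu=np.array([30.0, 40.0, 8.0]), sigma=np.eye(3),
                         n_train=100, quantile=0.95)


class TestFitGaussian:
    def test_tetrahedron_mean_is_centroid(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        base = np.array([30.0, 40.0, 8.0])
        m = fit_gaussian(pts + base)
        np.testing.assert_array_equal(m.mu, base)
        assert m.n_train == 4

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(1)
        mu = np.array([30.0, 40.0, 8.0])
        sigma = np.diag([4.0, 9.0, 4.0])
        x = rng.multivariate_normal(mu, sigma, size=2000)
        m = fit_gaussian(x)
        # tolerance ~ 4 sigma_max / sqrt(n)
        assert np.max(np.abs(m.mu - mu)) < 0.3
        assert np.allclose(m.sigma, sigma, atol=0.6)

    def test_identical_samples_degenerate(self):
        x = np.tile([30.0, 40.0, 8.0], (10, 1))
        with pytest.raises(DegenerateModelError):
            fit_gaussian(x)

    def test_coplanar_samples_degenerate(self, rng):
        x = rng.normal(0, 5, size=(50, 3))
        x[:, 2] = 2.0 * x[:, 0] - x[:, 1]  # rank-2 covariance
        with pytest.raises(DegenerateModelError):
            fit_gaussian(x)

    def test_too_few_samples(self):
        with pytest.raises(InputError):
            fit_gaussian(np.eye(3))


class TestPdf:
    def test_closed_form_at_mean_identity_sigma(self, identity_model):
        assert pdf(identity_model, identity_model.mu) == pytest.approx(
            (2 * np.pi) ** -1.5, abs=1e-12)

    def test_mode_at_mean(self, identity_model, rng):
        peak = pdf(identity_model, identity_model.mu)
        for _ in range(50):
            x = identity_model.mu + rng.normal(0, 3, 3)
            assert pdf(identity_model, x) <= peak

    def test_matches_scipy_oracle(self, rng):
        mu = rng.normal(30, 5, 3)
        sigma = random_spd(rng)
        m = GaussianModel(mu=mu, sigma=sigma, n_train=10)
        oracle = multivariate_normal(mean=mu, cov=sigma)
        for _ in range(20):
            x = mu + rng.normal(0, 8, 3)
            assert pdf(m, x) == pytest.approx(oracle.pdf(x), rel=1e-10)

    def test_integrates_to_one(self, identity_model):
        g = np.linspace(-6, 6, 25)
        h = g[1] - g[0]
        xs = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = np.array([pdf(identity_model, identity_model.mu + x) for x in xs])
        assert vals.sum() * h**3 == pytest.approx(1.0, abs=1e-3)


class TestMahalanobis:
    def test_zero_at_mean(self, identity_model):
        assert mahalanobis_sq(identity_model, identity_model.mu) == 0.0

    def test_euclidean_case(self, identity_model):
        x = identity_model.mu + np.array([1.0, 2.0, 2.0])
        assert mahalanobis_sq(identity_model, x) == pytest.approx(9.0, abs=1e-12)

    def test_matches_explicit_inverse_oracle(self, rng):
        for _ in range(20):
            mu = rng.normal(0, 10, 3)
            sigma = random_spd(rng)
            m = GaussianModel(mu=mu, sigma=sigma, n_train=10)
            x = mu + rng.normal(0, 10, 3)
            d = x - mu
            expected = float(d @ np.linalg.inv(sigma) @ d)
            assert mahalanobis_sq(m, x) == pytest.approx(expected, abs=1e-10)


class TestClassifyDataDriven:
    def test_mean_is_normal(self, identity_model):
        assert classify_data_driven(identity_model, identity_model.mu).label == "normal"

    def test_far_point_is_abnormal(self, identity_model):
        radius = np.sqrt(identity_model.chi2_threshold)
        x = identity_model.mu + np.array([10.0 * radius, 0.0, 0.0])
        d = classify_data_driven(identity_model, x)
        assert d.label == "abnormal"
        assert d.score == pytest.approx(10.0 * radius)

    def test_coverage_matches_quantile(self, rng):
        mu = np.array([30.0, 40.0, 8.0])
        sigma = np.diag([16.0, 9.0, 6.25])
        m = GaussianModel(mu=mu, sigma=sigma, n_train=500, quantile=0.95)
        draws = rng.multivariate_normal(mu, sigma, size=5000)
        normal = np.mean([classify_data_driven(m, x).label == "normal" for x in draws])
        se = np.sqrt(0.95 * 0.05 / 5000)
        assert abs(normal - 0.95) <= 2 * se


class TestClassifyKnowledge:
    @pytest.mark.parametrize("ce, label", [
        (19.0, "dysplastic"), (22.0, "borderline"), (30.0, "normal"),
        (20.0, "borderline"), (25.0, "borderline"),  # closed interval boundaries
    ])
    def test_ce_rule(self, ce, label):
        d = classify_knowledge(AngleTriplet(ce, 40.0, 5.0))
        assert d.label == label
        assert d.criterion == "knowledge_ce"

    def test_partitions_ce_axis_into_three_intervals(self):
        labels = [classify_knowledge(AngleTriplet(ce, 40, 5)).label
                  for ce in np.arange(0.0, 60.0001, 0.1)]
        changes = [(labels[i - 1], labels[i]) for i in range(1, len(labels))
                   if labels[i] != labels[i - 1]]
        assert changes == [("dysplastic", "borderline"), ("borderline", "normal")]

    def test_combined_tonnis_rule(self):
        t = KnowledgeThresholds()
        low_ce_high_tonnis = AngleTriplet(15.0, 45.0, 14.0)
        low_ce_low_tonnis = AngleTriplet(15.0, 45.0, 6.0)
        assert classify_knowledge(low_ce_high_tonnis, t, combine_tonnis=True).label == "dysplastic"
        assert classify_knowledge(low_ce_low_tonnis, t, combine_tonnis=True).label == "borderline"

    def test_invalid_thresholds(self):
        with pytest.raises(InputError):
            KnowledgeThresholds(ce_dysplastic_below=30.0, ce_normal_above=25.0)


class TestEllipsoidAxes:
    def test_diagonal_sigma(self):
        m = GaussianModel(mu=np.zeros(3), sigma=np.diag([9.0, 4.0, 1.0]), n_train=10)
        axes = ellipsoid_axes(m)
        scale = np.sqrt(chi2.ppf(0.95, 3))
        lengths = [h for _, h in axes]
        assert lengths == pytest.approx([3 * scale, 2 * scale, 1 * scale])
        # long axis along the first coordinate
        assert abs(axes[0][0] @ np.array([1.0, 0, 0])) == pytest.approx(1.0)

    def test_rotated_sigma_corotates(self, rng):
        th = 0.7
        r = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0],
                      [0, 0, 1.0]])
        sigma = r @ np.diag([25.0, 4.0, 1.0]) @ r.T
        m = GaussianModel(mu=np.zeros(3), sigma=sigma, n_train=10)
        axes = ellipsoid_axes(m)
        assert abs(axes[0][0] @ r[:, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_orthonormal_directions(self, rng):
        m = GaussianModel(mu=np.zeros(3), sigma=random_spd(rng), n_train=10)
        dirs = np.column_stack([d for d, _ in ellipsoid_axes(m)])
        np.testing.assert_allclose(dirs.T @ dirs, np.eye(3), atol=1e-10)


class TestSerialization:
    def test_round_trip(self, tmp_path, identity_model):
        p = tmp_path / "model.json"
        serialize_model(identity_model, p)
        back = load_model(p)
        np.testing.assert_array_equal(back.mu, identity_model.mu)
        np.testing.assert_array_equal(back.sigma, identity_model.sigma)
        assert back.n_train == identity_model.n_train
        assert back.quantile == identity_model.quantile

    def test_non_spd_sigma_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"mu": [0,0,0], "sigma": [[1,0,0],[0,-1,0],[0,0,1]],'
                     ' "n_train": 10, "quantile": 0.95, "version": "1"}')
        with pytest.raises(ModelSchemaError):
            load_model(p)

    def test_missing_field_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"mu": [0,0,0]}')
        with pytest.raises(ModelSchemaError, match="sigma"):
            load_model(p)
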