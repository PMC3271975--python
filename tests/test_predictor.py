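"""Standardize -> PCA -> LDA predictor: algebraic identities, closed-form
Gaussian posteriors, and cross-checks against an independent implementation."""

import numpy as np
import pytest

from leukorisk import predictor
from leukorisk.datamodel import SampleMetadata
from leukorisk.predictor import (
    LDAModel,
    RiskScore,
    fit_lda,
    fit_pca,
    lda_posterior,
    pca_scores,
    predict_scores,
    standardize_within_genes,
    train_predictor,
)
from leukorisk.triage import BiomarkerPanel

from conftest import make_matrix, make_metadata


class TestStandardize:
    def test_rows_become_mean0_sd1(self, rng):
        m = make_matrix(rng.normal(7, 3, size=(12, 9)))
        std = standardize_within_genes(m)
        np.testing.assert_allclose(std.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(std.values.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        m = make_matrix(rng.normal(size=(6, 7)))
        once = standardize_within_genes(m)
        twice = standardize_within_genes(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_row_zeroed_with_warning(self, rng):
        values = rng.normal(size=(3, 6))
        values[1] = 5.0
        with pytest.warns(RuntimeWarning, match="constant"):
            std = standardize_within_genes(make_matrix(values))
        assert np.all(std.values[1] == 0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            standardize_within_genes(make_matrix(np.ones((3, 1))))


class TestPca:
    def test_explained_fractions_normalized_and_sorted(self, rng):
        std = standardize_within_genes(make_matrix(rng.normal(size=(10, 15))))
        pca = fit_pca(std)
        frac = pca.explained_variance_fraction
        assert frac.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(frac) <= 1e-12)
        # orthonormal loadings
        np.testing.assert_allclose(pca.loadings.T @ pca.loadings, np.eye(3), atol=1e-10)

    def test_planted_single_factor_dominates(self, rng):
        f = rng.normal(size=20)
        loadings = rng.choice([-1.0, 1.0], size=15)
        values = np.outer(loadings, f) + rng.normal(0, 0.05, size=(15, 20))
        pca = fit_pca(standardize_within_genes(make_matrix(values)))
        assert pca.explained_variance_fraction[0] > 0.9
        assert pca.explained_variance_fraction[1] < 0.05

    def test_deterministic_with_fixed_sign_convention(self, rng):
        std = standardize_within_genes(make_matrix(rng.normal(size=(8, 10))))
        a, b = fit_pca(std), fit_pca(std)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for k in range(3):
            j = np.argmax(np.abs(a.loadings[:, k]))
            assert a.loadings[j, k] > 0

    def test_small_panel_rejected(self, rng):
        std = standardize_within_genes(make_matrix(rng.normal(size=(2, 10))))
        with pytest.raises(ValueError, match="need >= 3"):
            fit_pca(std)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        std = standardize_within_genes(make_matrix(rng.normal(size=(12, 18))))
        ours = fit_pca(std)
        sk = SkPCA(n_components=3).fit(std.values.T)
        np.testing.assert_allclose(
            ours.explained_variance_fraction, sk.explained_variance_ratio_, rtol=1e-8
        )
        # same subspace up to sign
        for k in range(3):
            dot = abs(float(ours.loadings[:, k] @ sk.components_[k]))
            assert dot == pytest.approx(1.0, abs=1e-8)


class TestLda:
    def test_well_separated_clouds_confident_posteriors(self, rng):
        scores = np.vstack(
            [rng.normal(-4, 0.5, size=(10, 3)), rng.normal(4, 0.5, size=(10, 3))]
        )
        labels = np.array([False] * 10 + [True] * 10)
        lda = fit_lda(scores, labels)
        post = lda_posterior(lda, scores)
        assert np.all(post[labels] >= 0.99)
        assert np.all(post[~labels] <= 0.01)

    def test_identical_class_means_give_half(self, rng):
        base = rng.normal(size=(6, 3))
        scores = np.vstack([base, base])
        labels = np.array([False] * 6 + [True] * 6)
        lda = fit_lda(scores, labels)
        np.testing.assert_allclose(lda_posterior(lda, scores), 0.5, atol=1e-12)

    def test_one_dimensional_closed_form(self):
        """Means +-1, unit variance, equal priors: P(high | x) is the
        logistic function of 2x, so x = 0.5 gives 1 / (1 + e^-1)."""
        lda = LDAModel(
            class_labels=("low", "high"),
            class_means=np.array([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            pooled_covariance=np.eye(3),
            priors=np.array([0.5, 0.5]),
        )
        post = lda_posterior(lda, np.array([[0.5, 0.0, 0.0]]))
        assert post[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)

    def test_three_dimensional_gaussian_bayes_oracle(self, rng):
        """Posterior matches the explicit Gaussian density ratio to 1e-8."""
        a = rng.normal(size=(3, 3))
        cov = a @ a.T + 0.5 * np.eye(3)
        mu_low, mu_high = rng.normal(size=3), rng.normal(size=3)
        priors = np.array([0.35, 0.65])
        lda = LDAModel(("low", "high"), np.vstack([mu_low, mu_high]), cov, priors)
        x = rng.normal(scale=2.0, size=(25, 3))
        inv = np.linalg.inv(cov)

        def density(v, mu):
            d = v - mu
            return np.exp(-0.5 * d @ inv @ d)

        expected = np.array(
            [
                priors[1] * density(v, mu_high)
                / (priors[0] * density(v, mu_low) + priors[1] * density(v, mu_high))
                for v in x
            ]
        )
        np.testing.assert_allclose(lda_posterior(lda, x), expected, atol=1e-8)

    def test_pooled_covariance_formula(self, rng):
        scores = rng.normal(size=(12, 3))
        labels = np.array([True] * 5 + [False] * 7)
        lda = fit_lda(scores, labels)
        resid_h = scores[labels] - scores[labels].mean(axis=0)
        resid_l = scores[~labels] - scores[~labels].mean(axis=0)
        expected = (resid_h.T @ resid_h + resid_l.T @ resid_l) / 10
        np.testing.assert_allclose(lda.pooled_covariance, expected, atol=1e-12)

    def test_tiny_class_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            fit_lda(rng.normal(size=(4, 3)), [True, False, False, False])

    def test_singular_covariance_ridge_regularized(self, caplog):
        import logging

        scores = np.zeros((8, 3))
        scores[:4, 0] = [0.0, 0.1, 0.0, 0.1]
        scores[4:, 0] = [1.0, 1.1, 1.0, 1.1]
        labels = np.array([False] * 4 + [True] * 4)
        with caplog.at_level(logging.WARNING, logger="leukorisk.predictor"):
            lda = fit_lda(scores, labels)
        assert "ridge" in caplog.text
        assert np.all(np.linalg.eigvalsh(lda.pooled_covariance) > 0)


class TestPredict:
    def _trained(self, cohort):
        panel_probes = cohort.truth.de_probes[:12]
        panel = BiomarkerPanel(tuple(panel_probes), "universal", "FH1")
        return panel, train_predictor(cohort.matrices["FH1"], cohort.metadata, panel)

    def test_self_prediction_reproduces_training_posteriors(self, fh_pair_cohort):
        panel, model = self._trained(fh_pair_cohort)
        train = fh_pair_cohort.matrices["FH1"]
        std = standardize_within_genes(train.subset_probes(panel.probe_ids))
        expected = lda_posterior(model.lda, pca_scores(model.pca, std))
        scores = predict_scores(model, train)
        np.testing.assert_allclose([s.posterior_high for s in scores], expected, atol=1e-12)

    def test_affine_rescaling_of_test_set_is_absorbed(self, fh_pair_cohort, rng):
        panel, model = self._trained(fh_pair_cohort)
        test = fh_pair_cohort.matrices["FH2"]
        scale = rng.uniform(0.5, 3.0, size=(test.n_probes, 1))
        shift = rng.normal(size=(test.n_probes, 1))
        warped = make_matrix(
            test.values * scale + shift,
            probe_ids=list(test.probe_ids),
            sample_ids=list(test.sample_ids),
        )
        a = [s.posterior_high for s in predict_scores(model, test)]
        b = [s.posterior_high for s in predict_scores(model, warped)]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_cross_cell_type_separation(self, fh_pair_cohort):
        panel, model = self._trained(fh_pair_cohort)
        scores = predict_scores(model, fh_pair_cohort.matrices["FH2"])
        by_id = {m.sample_id: m.subclass for m in fh_pair_cohort.metadata}
        high = [s.posterior_high for s in scores if by_id[s.sample_id] != "control"]
        low = [s.posterior_high for s in scores if by_id[s.sample_id] == "control"]
        assert np.mean(high) > np.mean(low)

    def test_missing_panel_probe_listed(self, fh_pair_cohort, rng):
        panel = BiomarkerPanel(
            (fh_pair_cohort.truth.de_probes[0], "ghost_at"), "universal", "FH1"
        )
        model_matrix = fh_pair_cohort.matrices["FH1"]
        with pytest.raises(KeyError, match="ghost_at"):
            model_matrix.subset_probes(panel.probe_ids)

    def test_save_load_round_trip(self, tmp_path, fh_pair_cohort):
        panel, model = self._trained(fh_pair_cohort)
        path = tmp_path / "model.json"
        predictor.save_predictor(model, path)
        back = predictor.load_predictor(path)
        test = fh_pair_cohort.matrices["FH2"]
        a = [s.posterior_high for s in predict_scores(model, test)]
        b = [s.posterior_high for s in predict_scores(back, test)]
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert back.panel.probe_ids == panel.probe_ids
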