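"""ComBat, CovBat, and traveling-subject harmonizers: parameter recovery,
null behavior, covariate protection, and closed-form agreement."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_two_site_location_scale, make_cohort
from sfplane import (
    CohortMatrix,
    PhenotypeTable,
    SimConfig,
    ValidationError,
    apply_combat,
    apply_traveling_subject,
    combat,
    covbat,
    fit_combat,
    fit_traveling_subject,
    generate_cohort,
    generate_traveling_companion,
    load_model,
    save_model,
)

QUIET = dict(noise_sd=0.05, subject_factor_sd=0.05)


def shifted_cohort(seed=42, offsets=(-0.3, 0.3), n=50):
    """Two-site cohort with a known uniform additive site offset per feature."""
    cfg = SimConfig(
        n_sites=2, subjects_per_site=n, n_rois=16, seed=seed, site_additive_sd=0.0,
        site_multiplicative_range=(1.0, 1.0), diagnosis_effect=0.0,
    )
    cohort, truth = generate_cohort(cfg, squash=False)
    site_idx = (cohort.sites == "site02").astype(int)
    gamma = np.array(offsets)[:, None] * np.ones((2, cohort.n_features))
    return cohort.with_features(cohort.features + gamma[site_idx]), gamma


class TestCombatFit:
    def test_single_site_rejected(self):
        cohort = make_cohort(np.random.default_rng(0).normal(size=(6, 3)), ["A"] * 6, 3)
        with pytest.raises(ValidationError, match="2 sites"):
            fit_combat(cohort)

    def test_collinear_covariate_named(self):
        r = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "site": ["A"] * 4 + ["B"] * 4,
                "age": [30.0] * 8,  # constant: collinear with the intercept
            }
        )
        cohort = CohortMatrix(r.normal(size=(8, 3)), PhenotypeTable(df), n_rois=3)
        with pytest.raises(ValidationError, match="age"):
            fit_combat(cohort, covariates=["age"])

    def test_recovers_known_additive_offsets(self):
        cohort, gamma = shifted_cohort()
        model = fit_combat(cohort)
        # gamma* lives on the standardized scale; sigma maps it back
        recovered = (model.gamma_star * np.sqrt(model.sigma2)).mean(axis=1)
        assert np.all(np.abs(recovered - gamma[:, 0]) < 0.05)

    def test_recovers_known_multiplicative_scales(self):
        r = np.random.default_rng(7)
        n, v = 100, 120
        delta_true = np.array([0.5, 2.0])
        sites = np.array(["A"] * n + ["B"] * n)
        y = r.normal(0.5, 0.3, v) + r.normal(0, 0.2, (2 * n, v)) * delta_true[
            (sites == "B").astype(int), None
        ]
        cohort = make_cohort(y, sites, 16)
        model = fit_combat(cohort, covariates=[])
        est = model.delta_star.mean(axis=1)
        # delta is identified only relative to the pooled residual scale
        w = np.array([0.5, 0.5])
        est_n = est / np.sqrt(w @ est**2)
        true_n = delta_true / np.sqrt(w @ delta_true**2)
        assert np.all(np.abs(est_n - true_n) / true_n < 0.15)


class TestCombatApply:
    def test_null_data_pass_through(self):
        cfg = SimConfig(
            n_sites=2, subjects_per_site=100, n_rois=16, seed=5,
            site_additive_sd=0.0, site_multiplicative_range=(1.0, 1.0), **QUIET,
        )
        cohort, _ = generate_cohort(cfg, squash=False)
        out, _ = combat(cohort)
        assert np.max(np.abs(out.features - cohort.features)) < 0.02

    def test_site_mean_gap_shrinks(self):
        cohort, _ = shifted_cohort(n=100)
        out, _ = combat(cohort)
        a, b = cohort.sites == "site01", cohort.sites == "site02"
        gap_pre = np.abs(
            cohort.features[a].mean(0) - cohort.features[b].mean(0)
        ).mean()
        gap_post = np.abs(out.features[a].mean(0) - out.features[b].mean(0)).mean()
        assert gap_post < 0.1 * gap_pre

    def test_pooled_mean_preserved_without_covariates(self):
        cohort, _ = shifted_cohort(n=40)
        out_plain, _ = combat(cohort, covariates=[], eb=False)
        assert np.max(
            np.abs(out_plain.features.mean(0) - cohort.features.mean(0))
        ) < 1e-6
        # shrinkage perturbs the pooled mean only slightly
        out_eb, _ = combat(cohort, covariates=[], eb=True)
        assert np.max(np.abs(out_eb.features.mean(0) - cohort.features.mean(0))) < 1e-3

    def test_unseen_site_rejected(self):
        cohort, _ = shifted_cohort(n=10)
        model = fit_combat(cohort)
        other = make_cohort(
            cohort.features[:4], ["siteXX"] * 4, cohort.n_rois
        )
        with pytest.raises(ValidationError, match="siteXX"):
            apply_combat(model, other)

    def test_diagnosis_effect_protected_while_site_gap_removed(self):
        cfg = SimConfig(
            n_sites=2, subjects_per_site=100, n_rois=16, seed=11,
            site_additive_sd=0.3, diagnosis_effect=0.2, diagnosis_fraction=0.5,
        )
        cohort, truth = generate_cohort(cfg, squash=False)
        out, _ = combat(cohort, covariates=["age", "sex", "diagnosis"])
        diag = cohort.phenotypes.data["diagnosis"] == "patient"
        edges = truth.diagnosis_edges

        def group_gap(feats, mask):
            return feats[np.asarray(mask)][:, edges].mean() - feats[
                np.asarray(~mask)
            ][:, edges].mean()

        gap_pre = group_gap(cohort.features, diag)
        gap_post = group_gap(out.features, diag)
        assert abs(gap_post - gap_pre) / abs(gap_pre) < 0.20
        a = cohort.sites == "site01"
        site_gap_pre = np.abs(
            cohort.features[a].mean(0) - cohort.features[~a].mean(0)
        ).mean()
        site_gap_post = np.abs(out.features[a].mean(0) - out.features[~a].mean(0)).mean()
        assert site_gap_post < 0.1 * site_gap_pre

    def test_matches_brute_force_single_feature_two_sites(self):
        r = np.random.default_rng(3)
        y = np.concatenate([r.normal(0.2, 1.0, 5), r.normal(-0.4, 2.0, 5)])
        sites = np.array(["A"] * 5 + ["B"] * 5)
        df = pd.DataFrame({"subject_id": [f"s{i}" for i in range(10)], "site": sites})
        # single feature: embed as a 1-column cohort via a 3-ROI matrix slot
        feats = np.column_stack([y, y, y])  # 3 features, each the same series
        cohort = CohortMatrix(feats, PhenotypeTable(df), n_rois=3)
        out, model = combat(cohort, covariates=[], eb=False)
        expected = brute_two_site_location_scale(y.copy(), sites)
        for col in range(3):
            assert np.allclose(out.features[:, col], expected, atol=1e-10)


class TestCovbat:
    def test_var_frac_validated(self):
        cohort, _ = shifted_cohort(n=10)
        with pytest.raises(ValidationError, match="var_frac"):
            covbat(cohort, var_frac=1.5)

    def test_needs_three_subjects(self):
        cohort = make_cohort(
            np.random.default_rng(0).normal(size=(2, 3)), ["A", "B"], 3
        )
        with pytest.raises(ValidationError):
            covbat(cohort)

    def test_full_var_frac_keeps_rank_components(self):
        cohort, _ = shifted_cohort(n=20)
        _, model = covbat(cohort, var_frac=1.0)
        j, v = 40, cohort.n_features
        # rank of the column-centered residual matrix
        assert model.K == min(j, v) - 1

    def test_equal_site_covariances_reduce_to_combat(self):
        cfg = SimConfig(
            n_sites=2, subjects_per_site=100, n_rois=16, seed=6,
            site_additive_sd=0.15, **QUIET,
        )
        cohort, _ = generate_cohort(cfg, squash=False)
        cb, _ = combat(cohort)
        cv, _ = covbat(cohort, var_frac=0.95)
        assert np.max(np.abs(cb.features - cv.features)) < 0.02

    @staticmethod
    def structured_covariance_cohort(seed=0, n=300, v=45,
                                     lam_a=(8.0, 3.0, 1.0), lam_b=(3.0, 1.0, 0.3)):
        """Two sites sharing residual principal axes but with site-specific
        variance profiles along them (plus ambient noise)."""
        r = np.random.default_rng(seed)
        k = len(lam_a)
        w = np.linalg.qr(r.normal(size=(v, v)))[0][:, :k]
        scores_a = r.normal(size=(n, k)) * np.sqrt(lam_a)
        scores_b = r.normal(size=(n, k)) * np.sqrt(lam_b)
        res_a = scores_a @ w.T + r.normal(0, 0.3, (n, v))
        res_b = scores_b @ w.T + r.normal(0, 0.3, (n, v))
        y = np.vstack([res_a, res_b]) + 0.5
        return make_cohort(y, ["A"] * n + ["B"] * n, 10), n

    def test_aligns_site_covariances_better_than_combat(self):
        cohort, n = self.structured_covariance_cohort(seed=0)

        def frob(feats):
            return np.linalg.norm(np.cov(feats[:n].T) - np.cov(feats[n:].T))

        pre = frob(cohort.features)
        cb, _ = combat(cohort, covariates=[])
        cv, model = covbat(cohort, covariates=[], var_frac=0.9)
        assert frob(cv.features) < 0.5 * pre
        assert frob(cv.features) < frob(cb.features)
        assert model.K >= 3

    def test_converges_to_combat_as_covariances_equalize(self):
        gaps = []
        for mix in (1.0, 0.5, 0.0):
            lam_b = tuple(a + mix * (b - a) for a, b in zip((8.0, 3.0, 1.0), (3.0, 1.0, 0.3)))
            cohort, _ = self.structured_covariance_cohort(seed=1, lam_b=lam_b)
            cb, _ = combat(cohort, covariates=[])
            cv, _ = covbat(cohort, covariates=[], var_frac=0.9)
            gaps.append(np.max(np.abs(cb.features - cv.features)))
        assert gaps[0] > gaps[1] > gaps[2]


class TestTravelingSubject:
    @staticmethod
    def companion(seed=0, **overrides):
        cfg = SimConfig(
            n_sites=12, subjects_per_site=2, n_rois=16, seed=seed,
            site_additive_sd=overrides.pop("site_additive_sd", 0.1),
            subject_factor_sd=0.2, noise_sd=overrides.pop("noise_sd", 0.05),
            **overrides,
        )
        _, truth = generate_cohort(cfg)
        comp = generate_traveling_companion(cfg, truth, n_travelers=9, squash=False)
        return comp, truth

    def test_recovers_measurement_bias(self):
        comp, truth = self.companion(seed=0)
        model = fit_traveling_subject(comp, lambda_l2=0.1)
        rmse = np.sqrt(np.mean((model.m_hat - truth.m_true) ** 2))
        assert rmse < 0.02
        assert np.allclose(model.m_hat.sum(axis=0), 0.0, atol=1e-8)

    def test_zero_bias_zero_noise_gives_null_bias(self):
        comp, _ = self.companion(seed=1, site_additive_sd=0.0, noise_sd=0.0)
        model = fit_traveling_subject(comp, lambda_l2=1e-10)
        assert np.max(np.abs(model.m_hat)) < 1e-8

    def test_bias_norm_shrinks_monotonically_in_lambda(self):
        comp, _ = self.companion(seed=2)
        norms = [
            np.linalg.norm(fit_traveling_subject(comp, lam).m_hat)
            for lam in (0.01, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_non_traveling_design_rejected(self):
        cohort = make_cohort(
            np.random.default_rng(0).normal(size=(6, 3)), ["A", "A", "A", "B", "B", "B"], 3
        )
        with pytest.raises(ValidationError, match="traveling"):
            fit_traveling_subject(cohort)

    def test_zero_model_is_identity_and_twice_subtracts_twice(self):
        comp, truth = self.companion(seed=3)
        model = fit_traveling_subject(comp)
        zero_model = fit_traveling_subject(comp)
        zero_model.m_hat = np.zeros_like(zero_model.m_hat)
        cfg = SimConfig(n_sites=12, subjects_per_site=2, n_rois=16, seed=3)
        cohort, _ = generate_cohort(cfg, squash=False)
        assert np.array_equal(
            apply_traveling_subject(zero_model, cohort).features, cohort.features
        )
        once = apply_traveling_subject(model, cohort)
        twice = apply_traveling_subject(model, once)
        idx = model.site_index(cohort.sites)
        assert np.allclose(
            twice.features, cohort.features - 2 * model.m_hat[idx], atol=1e-12
        )

    def test_site_gap_attributable_to_bias_mostly_removed(self):
        comp, truth = self.companion(seed=4, site_additive_sd=0.2)
        model = fit_traveling_subject(comp, lambda_l2=0.1)
        resid = truth.m_true - model.m_hat
        assert np.sqrt(np.mean(resid**2)) < 0.1 * np.sqrt(np.mean(truth.m_true**2))

    def test_unseen_site_rejected(self):
        comp, _ = self.companion(seed=5)
        model = fit_traveling_subject(comp)
        other = make_cohort(np.zeros((3, comp.n_features)), ["nowhere"] * 3, 16)
        with pytest.raises(ValidationError, match="nowhere"):
            apply_traveling_subject(model, other)


class TestSerialization:
    def test_models_round_trip_through_json(self, tmp_path):
        cohort, _ = shifted_cohort(n=15)
        _, cb = combat(cohort)
        _, cv = covbat(cohort, var_frac=0.9)
        comp, _ = TestTravelingSubject.companion(seed=6)
        tm = fit_traveling_subject(comp)
        for name, model in (("cb", cb), ("cv", cv), ("tm", tm)):
            path = tmp_path / f"{name}.json"
            save_model(model, path)
            loaded = load_model(path)
            assert type(loaded) is type(model)
        cb2 = load_model(tmp_path / "cb.json")
        assert np.allclose(cb2.gamma_star, cb.gamma_star)
        out1 = apply_combat(cb, cohort)
        out2 = apply_combat(cb2, cohort)
        assert np.allclose(out1.features, out2.features)
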