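"""Twin variance-component fits: outlier handling, ML recovery, AIC, LRT."""

import numpy as np
import pandas as pd
import pytest

from shapeasym.heritability import (
    TwinCohort,
    VarianceComponents,
    exclude_outliers_iqr,
    fit_variance_components,
    heritability_pipeline,
    residualize,
    select_model_aic,
    significance_lrt,
)
from shapeasym.synthetic import TwinSpec, generate_twin_phenotypes


def make_cohort(a2=0.6, c2=0.2, t2=0.0, e2=0.2, mz=300, dz=300, trios=0,
                seed=0, n_traits=1, **kw):
    spec = TwinSpec(n_mz_pairs=mz, n_dz_pairs=dz, n_sib_trios=trios,
                    a2=a2, c2=c2, t2=t2, e2=e2, seed=seed, **kw)
    df = generate_twin_phenotypes(spec, n_traits=n_traits)
    return TwinCohort(df), df


class TestIQR:
    def test_gross_outlier_removed(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 1000.0])
        kept, mask = exclude_outliers_iqr(vals)
        assert 1000.0 not in kept
        assert mask.sum() == 9

    def test_clean_data_unchanged(self):
        vals = np.random.default_rng(0).normal(size=50)
        kept, mask = exclude_outliers_iqr(vals)
        assert mask.all()

    def test_constant_data_all_removed_with_warning(self, caplog):
        kept, mask = exclude_outliers_iqr(np.ones(10))
        assert kept.size == 0
        assert "removed every value" in caplog.text

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="4"):
            exclude_outliers_iqr(np.array([1.0, 2.0, 3.0]))


class TestResidualize:
    def test_exact_covariate_relation_vanishes(self):
        age = np.linspace(20, 40, 30)
        np.testing.assert_allclose(residualize(2.0 * age, age[:, None]), 0.0,
                                   atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(100, 2))
        y = rng.normal(size=100)
        r = residualize(y, Z)
        assert abs(r @ Z[:, 0]) < 1e-8 and abs(r @ Z[:, 1]) < 1e-8
        assert abs(r.sum()) < 1e-8

    def test_rank_deficiency_rejected(self):
        Z = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            residualize(np.arange(10.0), Z)


class TestFit:
    def test_ace_parameter_recovery(self):
        cohort, _ = make_cohort(seed=0, mz=500, dz=500)
        fit = fit_variance_components(cohort, cohort.table["trait0001"].to_numpy(),
                                      "ACE")
        assert fit.a2 == pytest.approx(0.6, abs=0.05)
        assert fit.c2 == pytest.approx(0.2, abs=0.05)
        assert fit.e2 == pytest.approx(0.2, abs=0.05)

    def test_components_standardized(self):
        cohort, _ = make_cohort(seed=1)
        fit = fit_variance_components(cohort, cohort.table["trait0001"].to_numpy(),
                                      "ACTE")
        assert fit.a2 + fit.c2 + fit.t2 + fit.e2 == pytest.approx(1.0, abs=1e-6)

    def test_pure_environment_yields_e_model(self):
        cohort, _ = make_cohort(a2=0.0, c2=0.0, t2=0.0, e2=1.0, seed=2)
        y = cohort.table["trait0001"].to_numpy()
        fits = [fit_variance_components(cohort, y, m)
                for m in ("ACE", "AE", "E")]
        assert fits[0].a2 < 0.1
        assert select_model_aic(fits).model == "E"

    def test_full_model_likelihood_dominates_nested(self):
        cohort, _ = make_cohort(seed=3, trios=100)
        y = cohort.table["trait0001"].to_numpy()
        full = fit_variance_components(cohort, y, "ACTE")
        for m in ("ACE", "ATE", "CTE", "TE", "CE", "E"):
            assert full.loglik >= fit_variance_components(cohort, y, m).loglik - 1e-4

    def test_falconer_consistency(self):
        """Fitted a2 tracks 2(r_MZ - r_DZ) on large samples."""
        cohort, df = make_cohort(seed=4, mz=800, dz=800)
        wide = {z: df[df.zygosity == z].pivot_table(
            index="family", columns="role", values="trait0001")
            for z in ("MZ", "DZ")}
        r = {z: np.corrcoef(w["twin1"], w["twin2"])[0, 1]
             for z, w in wide.items()}
        falconer = 2 * (r["MZ"] - r["DZ"])
        fit = fit_variance_components(cohort, cohort.table["trait0001"].to_numpy(),
                                      "ACE")
        assert fit.a2 == pytest.approx(falconer, abs=0.05)

    def test_invalid_model_label_rejected(self):
        cohort, _ = make_cohort(seed=5, mz=30, dz=30)
        with pytest.raises(ValueError, match="model"):
            fit_variance_components(cohort, cohort.table["trait0001"].to_numpy(),
                                    "ACT")  # no E component


class TestSelectionAndLRT:
    @staticmethod
    def vc(model, loglik, n_params):
        return VarianceComponents(0.5, 0.0, 0.0, 0.5, model, loglik,
                                  2 * n_params - 2 * loglik, n_params, 1.0)

    def test_aic_tie_prefers_fewer_parameters(self):
        a = self.vc("ACE", -100.0, 4)
        b = self.vc("CE", -101.0, 3)  # identical AIC = 208
        assert select_model_aic([a, b]).model == "CE"

    def test_single_fit_returned(self):
        a = self.vc("E", -10.0, 2)
        assert select_model_aic([a]) is a

    def test_identical_logliks_give_p_one(self):
        full = self.vc("ACE", -50.0, 4)
        reduced = self.vc("CE", -50.0, 3)
        assert significance_lrt(full, reduced) == pytest.approx(1.0)

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            significance_lrt(self.vc("ATE", -50.0, 4), self.vc("CE", -50.0, 3))

    def test_strong_genetic_signal_detected(self):
        cohort, _ = make_cohort(a2=0.6, c2=0.0, t2=0.0, e2=0.4, seed=6,
                                mz=500, dz=500)
        y = cohort.table["trait0001"].to_numpy()
        full = fit_variance_components(cohort, y, "ACE")
        reduced = fit_variance_components(cohort, y, "CE")
        assert significance_lrt(full, reduced) < 1e-6

    def test_null_a_rejection_conservative(self):
        """With a2 = 0 truth, LRT rejections at alpha = 0.05 stay at or
        below nominal (boundary-constrained components)."""
        rejections = 0
        n_sim = 40
        for seed in range(n_sim):
            cohort, _ = make_cohort(a2=0.0, c2=0.3, t2=0.0, e2=0.7,
                                    mz=80, dz=80, seed=seed)
            y = cohort.table["trait0001"].to_numpy()
            full = fit_variance_components(cohort, y, "ACE")
            reduced = fit_variance_components(cohort, y, "CE")
            rejections += significance_lrt(full, reduced) <= 0.05
        assert rejections / n_sim <= 0.10


class TestPipeline:
    def test_sas_like_regime_low_h2(self):
        """E-dominated traits: h2 stays below 0.3 and few A-tests survive."""
        spec = TwinSpec(seed=8)  # defaults: a2=0.1, e2=0.9, imaging-cohort family counts
        df = generate_twin_phenotypes(spec, n_traits=8)
        cohort = TwinCohort(df)
        pheno = df.set_index("subject")[[c for c in df.columns
                                         if c.startswith("trait")]]
        res = heritability_pipeline(pheno, cohort)
        assert (res["h2"] < 0.3).all()
        assert (res["p_A_fdr"].fillna(1.0) < 0.05).sum() <= 2

    def test_multi_sibling_families_pruned(self):
        df = generate_twin_phenotypes(TwinSpec(n_mz_pairs=3, n_dz_pairs=0,
                                               n_sib_trios=0, seed=0))
        extra = df.iloc[[0]].copy()
        extra["subject"] = "extra_sib"
        extra["role"] = "sib"
        extra2 = extra.copy()
        extra2["subject"] = "extra_sib2"
        cohort = TwinCohort(pd.concat([df, extra, extra2], ignore_index=True))
        fam0 = cohort.table[cohort.table.family == df.family.iloc[0]]
        assert len(fam0) == 3  # two twins + one randomly kept sibling
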