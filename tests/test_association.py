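"""Association scan: panel filter, model fits, oracle equivalence, lambda."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import poolgwas as pg
from poolgwas.exceptions import ConfigError, InputError


class TestFilterPanel:
    def test_mixed_panel(self):
        panel = pd.DataFrame({
            "id": [f"v{i}" for i in range(10)],
            "chrom": ["1", "2", "X", "Y", "5", "6", "7", "8", "9", "10"],
            "pos": range(10),
            "maf": [0.2, 0.3, 0.2, 0.2, 0.005, 0.1, 0.1, 0.1, 0.1, 0.1],
        })
        kept, tally = pg.filter_panel(panel)
        assert len(kept) == 7
        assert tally == {"input": 10, "non_autosomal": 2, "low_maf": 1, "retained": 7}

    def test_all_pass_identity(self):
        panel = pd.DataFrame({"id": ["a"], "chrom": ["3"], "pos": [1], "maf": [0.3]})
        kept, _ = pg.filter_panel(panel)
        assert len(kept) == 1

    def test_maf_exactly_one_percent_retained(self):
        panel = pd.DataFrame({"id": ["a"], "chrom": ["3"], "pos": [1], "maf": [0.01]})
        kept, _ = pg.filter_panel(panel)
        assert len(kept) == 1  # the exclusion is strictly MAF < 1%

    def test_chr_prefix_and_mt_excluded(self):
        panel = pd.DataFrame({"id": ["a", "b"], "chrom": ["chr12", "MT"],
                              "pos": [1, 2], "maf": [0.3, 0.3]})
        kept, tally = pg.filter_panel(panel)
        assert list(kept["id"]) == ["a"]
        assert tally["non_autosomal"] == 1


class TestBonferroni:
    def test_reference_threshold(self):
        assert f"{pg.bonferroni_threshold(608550):.4g}" == "8.216e-08"

    def test_single_test(self):
        assert pg.bonferroni_threshold(1) == 0.05

    def test_invalid(self):
        with pytest.raises(ConfigError):
            pg.bonferroni_threshold(0)


class TestGenomicInflation:
    def test_uniform_grid_is_one(self):
        m = 10_001
        p = np.arange(1, m + 1) / (m + 1)
        assert pg.genomic_inflation(p) == pytest.approx(1.0, abs=1e-3)

    def test_halved_p_inflates(self):
        m = 10_001
        p = np.arange(1, m + 1) / (m + 1)
        assert pg.genomic_inflation(p / 2) > 1.0

    def test_too_few_values(self):
        with pytest.raises(InputError):
            pg.genomic_inflation([0.5])

    def test_out_of_range(self):
        with pytest.raises(InputError):
            pg.genomic_inflation([0.5, 0.0, 0.3])


class TestWaldFitOracle:
    def test_tau0_equals_statsmodels_weighted_logistic(self, six_pool_units, six_pool_baf):
        """tau^2=0 reduction equals an independent IRLS weighted-logistic fit."""
        sm = pytest.importorskip("statsmodels.api")
        spec = pg.ModelSpec(method="wald", tau2=0.0, covariates=("HT_prop",), factors=())
        rec = pg.fit_variant(six_pool_units, six_pool_baf, spec)
        assert rec.converged
        X = np.column_stack([np.ones(12), six_pool_baf, six_pool_units["HT_prop"]])
        res = sm.GLM(six_pool_units["T2D"].to_numpy(), X,
                     family=sm.families.Binomial(),
                     freq_weights=six_pool_units["n"].to_numpy()).fit()
        assert rec.beta == pytest.approx(res.params[1], rel=1e-6)
        assert rec.se == pytest.approx(res.bse[1], rel=1e-6)

    def test_tau0_equals_textbook_newton_raphson(self, six_pool_units, six_pool_baf):
        """Second independent oracle: hand-rolled Newton-Raphson IRLS."""
        X = np.column_stack([np.ones(12), six_pool_baf, six_pool_units["HT_prop"]])
        y = six_pool_units["T2D"].to_numpy(dtype=float)
        w = six_pool_units["n"].to_numpy(dtype=float)
        beta = np.zeros(3)
        for _ in range(100):
            mu = 1 / (1 + np.exp(-X @ beta))
            grad = X.T @ (w * (y - mu))
            hess = (X * (w * mu * (1 - mu))[:, None]).T @ X
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.abs(grad).max() < 1e-10:
                break
        se = np.sqrt(np.linalg.inv(hess)[1, 1])
        spec = pg.ModelSpec(method="wald", tau2=0.0, covariates=("HT_prop",), factors=())
        rec = pg.fit_variant(six_pool_units, six_pool_baf, spec)
        assert rec.beta == pytest.approx(beta[1], rel=1e-6)
        assert rec.se == pytest.approx(se, rel=1e-6)

    def test_wald_p_consistent_with_stat(self, six_pool_units, six_pool_baf):
        spec = pg.ModelSpec(method="wald", tau2=0.0, covariates=("HT_prop",), factors=())
        rec = pg.fit_variant(six_pool_units, six_pool_baf, spec)
        assert rec.p == pytest.approx(2 * stats.norm.sf(abs(rec.stat)))

    def test_constant_baf_flagged_aliased(self, six_pool_units):
        spec = pg.ModelSpec(method="wald", tau2=0.0, covariates=("HT_prop",), factors=())
        rec = pg.fit_variant(six_pool_units, np.full(12, 0.4), spec)
        assert rec.aliased and np.isnan(rec.p)

    def test_positive_tau2_shrinks_information(self, six_pool_units, six_pool_baf):
        spec0 = pg.ModelSpec(method="wald", tau2=0.0, covariates=("HT_prop",), factors=())
        spec5 = pg.ModelSpec(method="wald", tau2=5.0, covariates=("HT_prop",), factors=())
        rec0 = pg.fit_variant(six_pool_units, six_pool_baf, spec0)
        rec5 = pg.fit_variant(six_pool_units, six_pool_baf, spec5)
        assert rec5.se > rec0.se

    def test_t_reference_more_conservative(self, six_pool_units, six_pool_baf):
        specn = pg.ModelSpec(method="wald", tau2=0.0, covariates=("HT_prop",), factors=())
        spect = pg.ModelSpec(method="wald", tau2=0.0, covariates=("HT_prop",), factors=(),
                             reference="t")
        rn = pg.fit_variant(six_pool_units, six_pool_baf, specn)
        rt = pg.fit_variant(six_pool_units, six_pool_baf, spect)
        assert rt.p > rn.p


class TestScanContracts:
    def test_strong_effect_is_significant(self, default_scan_data):
        """Case-pool BAF shifted +0.15 -> p < 1e-6 at default noise."""
        cohort, panel, geno, plan, baf = default_scan_data
        case = (baf.units["T2D"] == 1).to_numpy()
        shifted = baf.baf.copy()
        shifted[case, :] = np.clip(shifted[case, :] + 0.15, 0, 1)
        b2 = pg.PoolBAFMatrix(baf=shifted, true_af=baf.true_af, units=baf.units,
                              variant_ids=baf.variant_ids)
        records, _ = pg.run_gwas(b2, pooling_error=False)
        p = records["p"].dropna()
        assert (p < 1e-6).mean() > 0.9

    def test_summary_significant_set_definition(self, default_scan_data):
        cohort, panel, geno, plan, baf = default_scan_data
        records, summary = pg.run_gwas(baf, panel=panel)
        assert summary.alpha_star == 0.05 / summary.m
        expect = set(records.loc[records["p"] < summary.alpha_star, "variant"].dropna())
        assert set(summary.significant) == expect
        assert summary.lambda_gc > 0

    def test_scan_deterministic(self, default_scan_data):
        cohort, panel, geno, plan, baf = default_scan_data
        r1, _ = pg.run_gwas(baf, pooling_error=False)
        r2, _ = pg.run_gwas(baf, pooling_error=False)
        pd.testing.assert_frame_equal(r1, r2)

    def test_outcome_class_requirement(self, six_pool_units, six_pool_baf):
        units = six_pool_units.copy()
        units["T2D"] = np.repeat([0, 0, 0, 0, 0, 1], 2)
        with pytest.raises(InputError, match="each outcome class"):
            pg.MixedLogitScan(units)

    def test_dimension_mismatch(self, six_pool_units):
        scanner = pg.MixedLogitScan(six_pool_units)
        with pytest.raises(InputError):
            scanner.scan(np.zeros((5, 3)))

    def test_score_beta_se_stat_consistent(self, default_scan_data):
        cohort, panel, geno, plan, baf = default_scan_data
        records, _ = pg.run_gwas(baf, pooling_error=False)
        ok = records["p"].notna()
        ratio = records.loc[ok, "beta"] / records.loc[ok, "se"]
        assert np.allclose(ratio, records.loc[ok, "stat"], rtol=1e-10)

    def test_aliased_columns_pruned_and_reported(self, six_pool_units):
        units = six_pool_units.copy()
        units["dup"] = units["HT_prop"]  # exact copy -> must be pruned
        spec = pg.ModelSpec(covariates=("HT_prop", "dup"), factors=())
        scanner = pg.MixedLogitScan(units, spec)
        assert "dup" in scanner.dropped_columns
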