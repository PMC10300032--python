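"""Association-core tests: logistic IRLS against closed forms and
statsmodels, BH-FDR against a brute-force oracle, QC filters, PCA-adjusted
score association and the replication-enrichment arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mthetqtl.association import (
    DEGENERATE,
    OK,
    SEPARATED,
    AssociationResult,
    ad_association,
    bh_fdr,
    build_design,
    cis_eqtl,
    fit_glm_binomial,
    fit_ols,
    genotype_pca,
    het_qtl,
    het_score_assoc,
    hwe_exact_test,
    qc_filter,
    replication_enrichment,
)
from mthetqtl.heteroplasmy import HetPresenceMatrix
from mthetqtl.mt_io import CovariateTable, GenotypeTable
from mthetqtl.synthetic_data import SimConfig, simulate_cohort


def _geno(calls, positions=None):
    calls = np.asarray(calls, dtype=float)
    n_var = calls.shape[1]
    positions = positions or list(range(100, 100 + n_var))
    return GenotypeTable(
        [f"S{i}" for i in range(calls.shape[0])],
        pd.DataFrame({"position": positions, "ref": ["A"] * n_var,
                      "alt": ["G"] * n_var, "rsid": [""] * n_var}),
        calls,
    )


class TestLogistic:
    def test_two_by_two_log_odds(self):
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8, float)
        g = np.array([1] * 10 + [0] * 10, float)
        X = np.column_stack([np.ones(20), g])
        fit = fit_glm_binomial(y, X, ["intercept", "genotype"])
        assert fit.coef[1] == pytest.approx(math.log(16.0), abs=1e-8)

    def test_constant_outcome_flagged(self):
        y = np.ones(30)
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        fit = fit_glm_binomial(y, X)
        assert fit.flag == DEGENERATE

    def test_separation_flagged_with_infinite_sentinel(self):
        g = np.array([0.0] * 15 + [1.0] * 15)
        y = g.copy()  # perfectly separated
        X = np.column_stack([np.ones(30), g])
        fit = fit_glm_binomial(y, X)
        assert fit.flag == SEPARATED
        assert np.isinf(fit.coef).any()

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0)])
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(np.linalg.LinAlgError, match="x2"):
            fit_glm_binomial(y, X)

    def test_matches_statsmodels_on_random_designs(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(23)
        for _ in range(5):
            n = 200
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            beta = rng.normal(scale=0.5, size=4)
            y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
            if y.min() == y.max():
                continue
            fit = fit_glm_binomial(y, X)
            ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
            np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)
            np.testing.assert_allclose(fit.p, ref.pvalues, atol=1e-6)

    def test_monte_carlo_unbiased(self):
        """Planted log-odds 1.0, n=400: the mean estimate is close to truth."""
        rng = np.random.default_rng(8)
        ests = []
        for _ in range(200):
            g = (rng.random(400) < 0.4).astype(float)
            p = 1 / (1 + np.exp(-(-2.0 + 1.0 * g)))
            y = (rng.random(400) < p).astype(float)
            X = np.column_stack([np.ones(400), g])
            fit = fit_glm_binomial(y, X)
            if fit.flag == OK:
                ests.append(fit.coef[1])
        assert abs(np.mean(ests) - 1.0) < 0.15


class TestOls:
    def test_two_group_slope_is_mean_difference(self):
        rng = np.random.default_rng(4)
        g = np.r_[np.zeros(30), np.ones(30)]
        y = rng.normal(size=60) + 0.7 * g
        X = np.column_stack([np.ones(60), g])
        fit = fit_ols(y, X)
        assert fit.coef[1] == pytest.approx(y[g == 1].mean() - y[g == 0].mean())

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(12)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 0.5, -0.3] + rng.normal(size=n)
        fit = fit_ols(y, X)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.p, ref.pvalues, atol=1e-12)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="identify"):
            fit_ols(np.zeros(3), np.ones((3, 3)))


def bh_oracle(p):
    """Definition-based BH: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        q[i] = best
    return q


class TestBhFdr:
    def test_hand_computed_vector(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.04, 0.8]))
        np.testing.assert_allclose(q, [0.04, 0.04, 4 * 0.04 / 3, 0.8], rtol=1e-12)

    def test_all_equal_ps_unchanged(self):
        q = bh_fdr(np.full(7, 0.3))
        np.testing.assert_allclose(q, 0.3)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_bruteforce_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(np.array(p)), bh_oracle(p), atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    def test_nan_passthrough(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_q_never_below_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(500)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()


class TestQc:
    def test_maf_boundary(self):
        # MAF exactly 0.09 removed; 0.10 retained (100 haploid samples)
        calls = np.zeros((100, 2))
        calls[:9, 0] = 1.0   # MAF 0.09
        calls[:10, 1] = 1.0  # MAF 0.10
        geno = _geno(calls)
        filtered, report = qc_filter(geno)
        assert len(filtered.variants) == 1
        assert filtered.variants.iloc[0]["position"] == 101
        assert report.removed_variants[0][1].startswith("maf<=")
        assert report.n_variants_retained + len(report.removed_variants) == 2

    def test_low_call_rate_sample_removed(self):
        calls = np.tile([0, 1, 0, 1, 0.0], (4, 1)).T  # 5 samples x 4 variants
        calls = calls.copy()
        calls[0, :3] = np.nan  # 25% call rate
        geno = _geno(calls)
        filtered, report = qc_filter(geno, maf_max_removed=0.0)
        assert ("S0", "call_rate<0.8") == report.removed_samples[0]
        assert len(filtered.samples) == 4

    def test_sex_discordance_removed(self):
        calls = np.tile([0, 1.0], (6, 1))
        geno = _geno(calls)
        cov = CovariateTable(pd.DataFrame(
            {"sex": ["F"] * 6, "genetic_sex": ["F"] * 5 + ["M"]},
            index=geno.samples))
        _, report = qc_filter(geno, cov, maf_max_removed=0.0)
        assert ("S5", "sex_discordance") in report.removed_samples

    def test_hwe_convention_removes_haploid_commons(self):
        # both alleles common but zero heterozygotes: the diploid convention
        # calls this a gross HWE violation, which is why the filter is opt-in
        calls = np.r_[np.zeros(30), np.ones(30)].reshape(-1, 1)
        geno = _geno(calls)
        _, rep_off = qc_filter(geno)
        assert not rep_off.removed_variants
        _, rep_on = qc_filter(geno, apply_hwe=True)
        assert rep_on.removed_variants[0][1].startswith("hwe_p<")


def hwe_oracle(n_ref, n_het, n_alt):
    """Exact HWE by direct comb-based enumeration (independent arithmetic)."""
    n = n_ref + n_het + n_alt
    n_rare = 2 * min(n_ref, n_alt) + n_het
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[h] = (
            math.comb(n, h)
            * math.comb(n - h, rare_hom)
            * 2**h
            / math.comb(2 * n, n_rare)
            * math.comb(n - h - rare_hom + rare_hom, rare_hom) ** 0
        )
    total = sum(probs.values())
    obs = probs[n_het] / total
    return sum(v / total for v in probs.values() if v / total <= obs * (1 + 1e-12))


class TestHwe:
    @pytest.mark.parametrize(
        "counts", [(20, 40, 20), (50, 10, 40), (5, 0, 95), (30, 30, 0), (0, 0, 10)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)

    def test_equilibrium_counts_not_rejected(self):
        # 0.5/0.5 alleles with het count at HW expectation
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_symmetric_in_allele_labels(self):
        assert hwe_exact_test(12, 30, 40) == pytest.approx(
            hwe_exact_test(40, 30, 12), rel=1e-12)


class TestScans:
    def test_het_qtl_misalignment_rejected(self, medium_cohort):
        c = medium_cohort
        pres = c.truth.het_presence
        pm = HetPresenceMatrix(pres, pres.sum(axis=1), 5)
        cov_missing = CovariateTable(c.covariates.data.iloc[:-5])
        with pytest.raises(ValueError, match="missing"):
            het_qtl(pm, c.genotypes, cov_missing)

    def test_het_qtl_maf_filter(self, medium_cohort):
        c = medium_cohort
        pres = c.truth.het_presence
        keep = [s for s in pres.columns if pres[s].sum() >= 5]
        pm = HetPresenceMatrix(pres[keep], pres.sum(axis=1), 5)
        rare_id = None
        maf = c.genotypes.maf()
        res = het_qtl(pm, c.genotypes, c.covariates, maf_min=0.05)
        tested = {r.predictor_id for r in res}
        for j, vid in enumerate(c.genotypes.variant_ids):
            assert (vid in tested) == (maf[j] >= 0.05)

    def test_ad_association_degenerate_when_single_class(self, medium_cohort):
        c = medium_cohort
        pres = c.truth.het_presence
        pm = HetPresenceMatrix(pres, pres.sum(axis=1), 5)
        cov = CovariateTable(c.covariates.data.assign(diagnosis=1))
        per_site, total = ad_association(pm, cov)
        assert all(r.flag == DEGENERATE for r in per_site)
        assert total.flag == DEGENERATE

    def test_cis_eqtl_two_group_closed_form(self):
        rng = np.random.default_rng(31)
        n = 40
        g = np.r_[np.zeros(20), np.ones(20)]
        counts = pd.DataFrame(
            {f"S{i}": [rng.poisson(200 * 2 ** (-0.5 * g[i]))] for i in range(n)},
            index=["gene1"], dtype=float)
        from mthetqtl.mt_io import ExpressionMatrix
        expr = ExpressionMatrix(counts)
        geno = _geno(g.reshape(-1, 1))
        cov = CovariateTable(pd.DataFrame(index=geno.samples))
        res = cis_eqtl(expr, geno, cov, covariate_columns=(), n_pcs=0)
        logc = np.log2(counts.to_numpy()[0] + 1)
        expected = logc[g == 1].mean() - logc[g == 0].mean()
        assert res[0].estimate == pytest.approx(expected, abs=1e-10)

    def test_cis_eqtl_min_expressed_filter(self, small_cohort):
        c = small_cohort
        counts = c.expression.counts.copy()
        counts.loc["MT-TY"] = 0.0
        counts.loc["MT-TY", counts.columns[:3]] = 5.0  # detected in 3 < 5 samples
        from mthetqtl.mt_io import ExpressionMatrix
        res = cis_eqtl(ExpressionMatrix(counts), c.genotypes, c.covariates)
        assert all(r.outcome_id != "MT-TY" for r in res)

    def test_het_score_assoc_planted_effect(self):
        rng = np.random.default_rng(17)
        ests = []
        for _ in range(100):
            n = 60
            g = (rng.random(n) < 0.5).astype(float)
            bg = (rng.random((n, 4)) < 0.3).astype(float)
            y = 0.7 * g + rng.normal(0, 1, n)
            geno = _geno(np.column_stack([g, bg]))
            scores = pd.DataFrame({"het_total": y}, index=geno.samples)
            res = het_score_assoc(scores, geno)
            ests.append(res[0].estimate)
        assert abs(np.mean(ests) - 0.7) < 0.35

    def test_het_score_assoc_degenerate_score(self):
        g = np.r_[np.zeros(10), np.ones(10)]
        geno = _geno(np.column_stack([g, 1 - g, (np.arange(20) % 2).astype(float)]))
        scores = pd.DataFrame({"het_total": np.zeros(20)}, index=geno.samples)
        res = het_score_assoc(scores, geno)
        assert all(r.flag == DEGENERATE for r in res)

    def test_genotype_pca_separates_outlier_group(self):
        # two-population mixture: the main panel carries low-frequency
        # variants, the 3-sample divergent lineage carries their flips, so
        # ancestry is the dominant axis of genotype variance
        cohort = simulate_cohort(
            SimConfig(n_samples=60, seed=3, with_pileups=False,
                      n_ancestry_outliers=3,
                      background_positions=tuple(range(1000, 5000, 100)),
                      background_freq_range=(0.05, 0.2))
        )
        pcs = genotype_pca(cohort.genotypes, k=2)
        outliers = pcs[-3:, 0]
        rest = pcs[:-3, 0]
        lo, hi = rest.min(), rest.max()
        assert all((o < lo) | (o > hi) for o in outliers)


class TestEnrichment:
    def _results(self, n, p_values, directions):
        return [
            AssociationResult(f"v{i}", f"g{i}", directions[i] * 1.0, 0.1, p_values[i])
            for i in range(n)
        ]

    def _reference(self, n, directions):
        return pd.DataFrame(
            {"predictor_id": [f"v{i}" for i in range(n)],
             "outcome_id": [f"g{i}" for i in range(n)],
             "direction": directions}
        )

    def test_expected_null_is_exact_product(self):
        rng = np.random.default_rng(0)
        p = rng.random(764)
        d = rng.choice([-1, 1], 764)
        enr = replication_enrichment(self._results(764, p, d), self._reference(764, d))
        assert enr.expected_null == 764 * 0.01
        assert enr.n_tested == 764

    def test_null_counts_not_significant(self):
        rng = np.random.default_rng(1)
        p = rng.random(764)
        d = rng.choice([-1, 1], 764)
        enr = replication_enrichment(self._results(764, p, d), self._reference(764, d))
        assert enr.p_enrichment > 0.05

    def test_shared_effects_detected(self):
        rng = np.random.default_rng(2)
        p = rng.random(764)
        true = rng.random(764) < 0.15
        p[true] = rng.random(true.sum()) * 0.005
        d = rng.choice([-1, 1], 764)
        enr = replication_enrichment(self._results(764, p, d), self._reference(764, d))
        assert enr.p_enrichment < 1e-3
        assert enr.sign_concordance == 1.0

    def test_empty_overlap_rejected(self):
        res = self._results(3, [0.5] * 3, [1] * 3)
        ref = pd.DataFrame({"predictor_id": ["zz"], "outcome_id": ["zz"],
                            "direction": [1]})
        with pytest.raises(ValueError, match="overlap"):
            replication_enrichment(res, ref)


class TestDesign:
    def test_one_hot_drops_reference_level(self):
        cov = pd.DataFrame({"study": ["ROS", "MAP", "ROS"], "age_death": [80, 85, 90.0]})
        X, names = build_design(cov, ["study", "age_death"], n_pcs=0)
        assert names == ["study_ROS", "age_death"]

    def test_constant_columns_dropped(self):
        cov = pd.DataFrame({"study": ["ROS"] * 3, "age_death": [80, 85, 90.0]})
        X, names = build_design(cov, ["study", "age_death"], n_pcs=0)
        assert names == ["age_death"]
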