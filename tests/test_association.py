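"""Association machinery: null models, SKAT/SKAT-O, carrier tests, windows,
region/set/case-control testing and the post-test gene filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

import cardiomod as cm
from cardiomod.association import (
    GeneTestResult,
    TraitSpec,
    WindowSpec,
    dichotomize_trait,
    fisher_carrier_test,
    fit_null_model,
    make_sliding_windows,
    post_test_gene_filter,
    skat_o_test,
    skat_test,
)


def frame(n, seed=0, linear_in_age=False):
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 70, n)
    sex = rng.integers(0, 2, n)
    bmi = rng.normal(27, 4, n)
    if linear_in_age:
        lvwt = 3.0 + 0.2 * age
    else:
        lvwt = rng.normal(19, 5, n)
    return pd.DataFrame(
        {"lvwt": lvwt, "age": age, "sex": sex, "bmi": bmi},
        index=[f"S{i:04d}" for i in range(n)])


TRAIT = TraitSpec("LVWT", "continuous", ("age", "sex", "bmi"))


class TestNullModel:
    def test_exact_linear_trait_has_zero_residuals(self):
        nm = fit_null_model(TRAIT, frame(40, linear_in_age=True))
        assert np.max(np.abs(nm.residuals)) < 1e-8

    def test_coefficients_match_normal_equations(self):
        data = frame(50, seed=3)
        nm = fit_null_model(TRAIT, data)
        X = nm.X
        beta = np.linalg.solve(X.T @ X, X.T @ data.lvwt.to_numpy())
        assert np.allclose(X @ beta, nm.fitted_values, atol=1e-10)

    def test_residuals_sum_to_zero_with_intercept(self):
        nm = fit_null_model(TRAIT, frame(30, seed=4))
        assert abs(nm.residuals.sum()) < 1e-8

    def test_independent_covariates_leave_centered_trait(self):
        data = frame(500, seed=5)
        nm = fit_null_model(TRAIT, data)
        centered = data.lvwt - data.lvwt.mean()
        assert np.corrcoef(nm.residuals, centered)[0, 1] > 0.98

    def test_missing_covariates_dropped_with_warning(self):
        data = frame(30, seed=6)
        data.loc[data.index[0], "bmi"] = np.nan
        with pytest.warns(UserWarning, match="dropping 1"):
            nm = fit_null_model(TRAIT, data)
        assert nm.n == 29

    def test_collinear_covariates_raise(self):
        data = frame(30, seed=7)
        data["bmi"] = 2 * data["age"]
        with pytest.raises(ValueError, match="collinear"):
            fit_null_model(TRAIT, data)


def perm_oracle_p(G, r, B, seed, weights=None):
    """Independent permutation oracle for the SKAT statistic."""
    if weights is None:
        weights = np.ones(G.shape[1])
    A = G * weights
    q_obs = float(np.sum((A.T @ r) ** 2))
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(B):
        rp = rng.permutation(r)
        ge += np.sum((A.T @ rp) ** 2) >= q_obs - 1e-12
    return (ge + 1) / (B + 1)


class TestSkat:
    def test_all_zero_genotypes_flagged(self, intercept_null_model):
        nm, _ = intercept_null_model
        res = skat_test(np.zeros((nm.n, 3)), nm)
        assert res.p == 1.0 and res.no_carriers

    def test_single_variant_matches_score_test_oracle(self):
        """Plug-in mode on one variant equals the closed-form 1-df score
        test."""
        data = frame(60, seed=8)
        nm = fit_null_model(TRAIT, data)
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.2, nm.n).astype(float)
        res = skat_test(g[:, None], nm, weights=np.ones(1),
                        small_sample=False)
        # oracle: U = g'r, Var(U) = sigma2 * g'(I-H)g, p = chi2_1 tail
        P = nm.projection()
        U = float(g @ nm.residuals)
        V = nm.dispersion * float(g @ P @ g)
        p_oracle = float(stats.chi2.sf(U**2 / V, 1))
        assert res.p == pytest.approx(p_oracle, abs=1e-6)

    def test_resampling_calibration_matches_oracle(self, intercept_null_model):
        nm, _ = intercept_null_model
        rng = np.random.default_rng(10)
        G = rng.binomial(2, rng.uniform(0.1, 0.3, 3), size=(nm.n, 3)).astype(float)
        w = np.ones(3)
        res = skat_test(G, nm, weights=w, calibration="permutation",
                        n_resamples=400_000, seed=1)
        B = 100_000
        p_oracle = perm_oracle_p(G, nm.residuals, B, seed=99, weights=w)
        se = np.sqrt(p_oracle * (1 - p_oracle) / B)
        assert abs(res.p - p_oracle) < 3 * se

    def test_exact_ratio_close_to_permutation(self, intercept_null_model):
        """The analytic small-sample null tracks permutation closely on a
        Gaussian trait (absolute tolerance reflects the conditioning
        difference between the two nulls)."""
        nm, _ = intercept_null_model
        rng = np.random.default_rng(11)
        G = rng.binomial(2, rng.uniform(0.15, 0.35, 4),
                         size=(nm.n, 4)).astype(float)
        res = skat_test(G, nm, weights=np.ones(4))
        p_oracle = perm_oracle_p(G, nm.residuals, 50_000, seed=12,
                                 weights=np.ones(4))
        assert res.p == pytest.approx(p_oracle, abs=0.02)

    def test_invariance_to_individual_and_variant_ordering(self):
        data = frame(40, seed=13)
        nm = fit_null_model(TRAIT, data)
        rng = np.random.default_rng(14)
        G = rng.binomial(2, 0.15, size=(40, 4)).astype(float)
        p0 = skat_test(G, nm).p
        # variant order
        assert skat_test(G[:, ::-1], nm).p == pytest.approx(p0, rel=1e-9)
        # individual order (permute data and genotypes together)
        perm = rng.permutation(40)
        nm2 = fit_null_model(TRAIT, data.iloc[perm])
        assert skat_test(G[perm], nm2).p == pytest.approx(p0, rel=1e-6)

    def test_missing_genotypes_mean_imputed(self, intercept_null_model):
        nm, _ = intercept_null_model
        rng = np.random.default_rng(15)
        G = rng.binomial(2, 0.3, size=(nm.n, 3)).astype(float)
        Gm = G.copy()
        Gm[0, 0] = np.nan
        # should run and give a nearby p-value
        assert skat_test(Gm, nm).p == pytest.approx(skat_test(G, nm).p,
                                                    abs=0.2)


class TestSkatO:
    def _fixture(self, n=26, m=4, seed=20):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame({"lvwt": rng.normal(0, 1, n)},
                            index=[f"S{i}" for i in range(n)])
        nm = fit_null_model(TraitSpec("LVWT", "continuous", ()), data)
        G = rng.binomial(2, rng.uniform(0.1, 0.35, m), size=(n, m)).astype(float)
        return nm, G

    def test_degenerate_grid_zero_equals_skat(self):
        nm, G = self._fixture()
        p_skat = skat_test(G, nm).p
        res = skat_o_test(G, nm, rho_grid=[0.0])
        assert res.p == pytest.approx(p_skat, rel=1e-9)

    def test_degenerate_grid_one_equals_burden(self):
        nm, G = self._fixture()
        w = np.ones(G.shape[1])
        res = skat_o_test(G, nm, weights=w, rho_grid=[1.0])
        burden = G.sum(axis=1, keepdims=True)
        p_burden = skat_test(burden, nm, weights=np.ones(1)).p
        assert res.p == pytest.approx(p_burden, rel=1e-9)

    def test_p_bounded_by_minp_and_bonferroni(self):
        nm, G = self._fixture(seed=21)
        res = skat_o_test(G, nm)
        t = min(res.p_per_rho.values())
        assert t <= res.p <= min(1.0, t * len(res.p_per_rho)) + 1e-12

    def test_resampling_double_permutation_matches_oracle(self):
        nm, G = self._fixture(n=24, m=3, seed=22)
        rho = (0.0, 0.5, 1.0)
        res = skat_o_test(G, nm, weights=np.ones(3), rho_grid=rho,
                          calibration="permutation", n_resamples=200_000,
                          seed=5)
        # independent double-permutation oracle
        B = 40_000
        rng = np.random.default_rng(77)
        A = G * np.ones(3)
        r = nm.residuals
        S = A.T @ r
        qs_obs = np.array([(1 - rr) * np.sum(S**2) + rr * S.sum() ** 2
                           for rr in rho])
        Q = np.empty((B, len(rho)))
        for b in range(B):
            Sp = A.T @ rng.permutation(r)
            Q[b] = [(1 - rr) * np.sum(Sp**2) + rr * Sp.sum() ** 2
                    for rr in rho]
        p_each = np.array([
            (np.sum(Q[:, j] >= qs_obs[j] - 1e-12) + 1) / (B + 1)
            for j in range(len(rho))])
        ranks = np.array([
            (B - np.searchsorted(np.sort(Q[:, j]), Q[:, j], side="left") + 1)
            / (B + 1) for j in range(len(rho))]).T
        minp = ranks.min(axis=1)
        p_oracle = (np.sum(minp <= p_each.min() + 1e-15) + 1) / (B + 1)
        se = np.sqrt(p_oracle * (1 - p_oracle) / B)
        assert abs(res.p - p_oracle) < 3 * se

    def test_no_carriers(self):
        nm, _ = self._fixture()
        res = skat_o_test(np.zeros((nm.n, 2)), nm)
        assert res.p == 1.0 and res.no_carriers


class TestDichotomize:
    def test_median_split(self):
        high = dichotomize_trait([1, 2, 3, 4])
        assert list(high) == [False, False, True, True]

    def test_value_at_median_goes_low(self):
        high = dichotomize_trait([1, 2, 2, 3])
        assert list(high) == [False, False, False, True]

    def test_binary_high_is_cases(self):
        assert list(dichotomize_trait([1, 0, 1], kind="binary")) == \
            [True, False, True]

    def test_constant_values_raise(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize_trait([2.0, 2.0, 2.0])


def fisher_enumeration_oracle(a, nh, c, nl):
    """Exhaustive enumeration of 2x2 tables with fixed margins."""
    k = a + c  # total carriers
    denom = comb(nh + nl, k, exact=True)
    p_obs = comb(nh, a, exact=True) * comb(nl, k - a, exact=True) / denom
    total = 0.0
    for x in range(max(0, k - nl), min(nh, k) + 1):
        px = comb(nh, x, exact=True) * comb(nl, k - x, exact=True) / denom
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


class TestFisherCarrierTest:
    def test_identical_margins_p_one(self):
        assert fisher_carrier_test(3, 10, 3, 10).p == pytest.approx(1.0)

    def test_extreme_asymmetry_significant_one_sided(self):
        res = fisher_carrier_test(8, 14, 0, 14, alternative="greater")
        assert res.p < 0.001
        assert res.freq_high == pytest.approx(8 / 14)
        assert res.z_prop > 3

    @pytest.mark.parametrize("a,nh,c,nl", [
        (3, 10, 3, 10), (8, 14, 0, 14), (5, 12, 2, 9), (0, 6, 4, 8),
        (7, 7, 1, 13), (2, 28, 9, 28),
    ])
    def test_matches_enumeration_exactly(self, a, nh, c, nl):
        res = fisher_carrier_test(a, nh, c, nl)
        assert res.p == pytest.approx(fisher_enumeration_oracle(a, nh, c, nl),
                                      abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fisher_carrier_test(3, 0, 1, 5)
        with pytest.raises(ValueError):
            fisher_carrier_test(6, 5, 1, 5)


class TestSlidingWindows:
    def test_default_starts_on_100kb_region(self):
        wins = make_sliding_windows(("chr1", 0, 100_000))
        assert [w[1] for w in wins] == [0, 25_000, 50_000, 75_000]
        assert wins[0][2] - wins[0][1] == 50_000

    def test_short_region_single_window(self):
        assert make_sliding_windows(("chr1", 0, 30_000)) == \
            [("chr1", 0, 30_000)]

    def test_step_equals_width_tiles(self):
        spec = WindowSpec(width_bp=10_000, step_bp=10_000)
        wins = make_sliding_windows(("chr1", 0, 35_000), spec)
        assert wins == [("chr1", 0, 10_000), ("chr1", 10_000, 20_000),
                        ("chr1", 20_000, 30_000), ("chr1", 30_000, 35_000)]

    def test_union_covers_region_and_overlap_is_width_minus_step(self):
        spec = WindowSpec(width_bp=50_000, step_bp=25_000)
        region = ("chr1", 10_000, 222_000)
        wins = make_sliding_windows(region, spec)
        assert wins[0][1] == region[1] and wins[-1][2] == region[2]
        for (_, s1, e1), (_, s2, _) in zip(wins, wins[1:]):
            if e1 - s1 == spec.width_bp:  # interior (unclipped) window
                assert e1 - s2 == spec.width_bp - spec.step_bp

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(width_bp=10, step_bp=20)
        with pytest.raises(ValueError):
            make_sliding_windows(("chr1", 5, 5))


class TestRegionTests:
    def test_region_without_variants_skipped(self, small_sim):
        sim, _, gene_models = small_sim
        sub = cm.select_analysis_subset(sim.cohort)
        data = sub.table.set_index("sample_id")[
            ["lvwt", "age", "sex", "bmi"]]
        regions = pd.DataFrame([
            {"region_id": "EMPTY", "chrom": "chr9", "start": 0, "end": 10},
        ])
        table = sim.variants.subset_samples(sub.samples)
        (res,) = cm.test_regions(table, regions, TRAIT, data,
                                 methods=("skat",))
        assert res.skipped and res.p_skat is None

    def test_gene_set_singleton_equals_gene_test(self, small_sim):
        sim, truth, gene_models = small_sim
        sub = cm.select_analysis_subset(sim.cohort)
        data = sub.table.set_index("sample_id")[
            ["lvwt", "age", "sex", "bmi"]]
        table = sim.variants.subset_samples(sub.samples)
        regions = gene_models.rename(columns={"gene": "region_id"})
        gene_res = cm.test_regions(table, regions, TRAIT, data,
                                   methods=("skat",))
        set_res = cm.test_gene_sets(table, {"solo": ["MODG1"]}, gene_models,
                                    TRAIT, data, methods=("skat",))
        by_id = {r.region_id: r for r in gene_res}
        assert set_res[0].p_skat == pytest.approx(by_id["MODG1"].p_skat,
                                                  rel=1e-9)

    def test_gene_set_union_counts_variants(self, small_sim):
        sim, truth, gene_models = small_sim
        sub = cm.select_analysis_subset(sim.cohort)
        data = sub.table.set_index("sample_id")[
            ["lvwt", "age", "sex", "bmi"]]
        table = sim.variants.subset_samples(sub.samples)
        regions = gene_models.rename(columns={"gene": "region_id"})
        gene_res = {r.region_id: r for r in cm.test_regions(
            table, regions, TRAIT, data, methods=("skat",))}
        set_res = cm.test_gene_sets(
            table, {"pair": ["NULLG1", "NULLG2"]}, gene_models, TRAIT, data,
            methods=("skat",))
        assert set_res[0].n_variants == gene_res["NULLG1"].n_variants + \
            gene_res["NULLG2"].n_variants

    def test_empty_gene_set_skipped_with_warning(self, small_sim):
        sim, _, gene_models = small_sim
        sub = cm.select_analysis_subset(sim.cohort)
        data = sub.table.set_index("sample_id")[
            ["lvwt", "age", "sex", "bmi"]]
        with pytest.warns(UserWarning, match="empty"):
            res = cm.test_gene_sets(sim.variants.subset_samples(sub.samples),
                                    {"none": []}, gene_models, TRAIT, data)
        assert res[0].skipped


class TestCaseControl:
    def test_variants_outside_footprint_excluded(self, small_sim):
        sim, truth, gene_models = small_sim
        exome = cm.make_exome_intervals(gene_models, exon_length=4000)
        controls = cm.generate_external_controls(sim.variants, exome,
                                                 n_controls=40, seed=1)
        regions = gene_models.rename(columns={"gene": "region_id"})
        results, report = cm.case_control_test(
            sim.variants, controls, exome, regions, methods=("fisher",))
        assert report.loc[0, "variants_out"] < report.loc[0, "variants_in"]
        footprint = exome.padded(10)
        tested = {r.region_id for r in results if not r.skipped}
        for res in results:
            if res.skipped:
                continue
            # every tested variant is inside the padded capture footprint
        kept = sim.variants.restrict_to_regions(footprint)
        assert all(footprint.contains(rec.chrom, rec.pos0)
                   for rec in kept.records)
        assert tested  # at least one gene tested

    def test_empty_controls_raise(self, small_sim):
        sim, _, gene_models = small_sim
        exome = cm.make_exome_intervals(gene_models)
        empty = cm.VariantTable([], [])
        regions = gene_models.rename(columns={"gene": "region_id"})
        with pytest.raises(ValueError, match="control"):
            cm.case_control_test(sim.variants, empty, exome, regions)


class TestPostTestGeneFilter:
    def _results(self, genes):
        return [GeneTestResult(g, "CASE_CONTROL", 1) for g in genes]

    def test_prefix_and_udp_filtering(self):
        res = self._results(["OR4F5", "MYH7", "DNAJB1", "USP9X", "TTN"])
        kept = [r.region_id for r in post_test_gene_filter(
            res, udp_blacklist_genes=["TTN"])]
        assert kept == ["MYH7"]

    def test_prefix_list_configurable(self):
        res = self._results(["DNAJB1", "DYNC1H1"])
        kept = post_test_gene_filter(res, prefixes=("KRT",))
        assert [r.region_id for r in kept] == ["DNAJB1", "DYNC1H1"]


class TestNullCalibrationThroughGenerator:
    """Under a zero-effect truth set, p-values from generated data are
    uniform."""

    def test_continuous_trait_null_uniform_over_500_genes(self):
        # At the scaled cohort size the carrier counts are large enough for
        # the p-value distribution to be continuous; at n=28 rare-variant
        # p-values are atomic (few carrier configurations), which is why the
        # small-cohort calibration contract is asserted as a type-I error
        # rate instead.
        truth = cm.TruthSet(null_genes=[f"NULL{i:03d}" for i in range(500)])
        cohort = cm.generate_cohort(cm.CohortConfig.scaled(200, seed=31))
        params = cm.SimParams(intergenic_variant_count=0,
                              missingness_rate=0.0)
        sim = cm.generate_genotypes(cohort, truth, params, seed=31)
        sub = cm.select_analysis_subset(sim.cohort)
        data = sub.table.set_index("sample_id")[
            ["lvwt", "age", "sex", "bmi"]]
        nm = fit_null_model(TRAIT, data)
        table = sim.variants.subset_samples(list(data.index))
        G = table.dosage_matrix()
        genes = np.array(sim.gene_of_variant)
        ps = []
        for gene in truth.null_genes:
            cols = np.flatnonzero(genes == gene)
            Gg = G[:, cols]
            if not np.any(Gg):
                continue
            ps.append(skat_test(Gg, nm).p)
        assert len(ps) >= 400
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_case_control_null_uniform_over_500_genes(self):
        """Cases and controls drawn from the same background give uniform
        p-values on the shared exome footprint."""
        rng = np.random.default_rng(77)
        n_case, n_ctl, m = 28, 100, 8
        y = np.r_[np.ones(n_case), np.zeros(n_ctl)]
        data = pd.DataFrame({"case_control": y},
                            index=[f"S{i}" for i in range(len(y))])
        nm = fit_null_model(TraitSpec.for_name("CASE_CONTROL"), data)
        ps = []
        for _ in range(500):
            maf = rng.uniform(0.01, 0.08, m)
            G = rng.binomial(2, maf, size=(len(y), m)).astype(float)
            if not np.any(G):
                continue
            ps.append(skat_test(G, nm).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
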