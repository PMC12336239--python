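"""Synthetic-data generators: marginals, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

import cardiomod as cm
from cardiomod.sv import reciprocal_overlap


class TestGenerateCohort:
    def test_default_marginals_exact(self, default_cohort):
        df = default_cohort.table
        assert len(df) == 48
        assert df.diagnosis.value_counts()["hypertrophic"] == 42
        assert df.morphology.value_counts().to_dict() == {
            "Asymmetric septal hypertrophy": 30,
            "Concentric hypertrophy": 6,
            "ECG+/LVH-": 3,
            "Isolated noncompaction": 3,
            "Apical hypertrophy": 2,
            "Inferior hypertrophy": 2,
            "Burnt-out hypertrophic": 1,
            "Dilated": 1,
        }
        assert df.sex.value_counts().to_dict() == {"F": 24, "M": 24}
        assert df.ancestry.value_counts()["Caucasian"] == 34

    def test_family_structure(self, default_cohort):
        df = default_cohort.table
        related = df[~df.is_proband]
        assert len(related) == 8  # 48 individuals, 40 unrelated
        assert df.family_id.nunique() == 40
        sizes = df.groupby("family_id").size()
        assert (sizes[sizes > 1].sub(1) <= 3).all()
        # every relative points at a proband of the same family
        for row in related.itertuples():
            proband = df[(df.family_id == row.family_id) & df.is_proband]
            assert list(proband.sample_id) == [row.related_to]

    def test_planted_analysis_subset_size(self, default_cohort):
        sub = cm.select_analysis_subset(default_cohort)
        assert len(sub) == default_cohort.analysis_eligible_probands == 28

    def test_empty_cohort(self):
        cohort = cm.generate_cohort(cm.CohortConfig(
            n_individuals=0, morphology_counts={}, diagnosis_counts={},
            sex_counts={}, ancestry_counts={}))
        assert len(cohort) == 0

    def test_trait_bounds_respected(self, default_cohort):
        df = default_cohort.table
        assert df.ef.between(5, 90).all()
        assert df.lvotg.between(0, 150).all()

    def test_deterministic_byte_identical(self):
        a = cm.generate_cohort(cm.CohortConfig(seed=3)).to_tsv()
        b = cm.generate_cohort(cm.CohortConfig(seed=3)).to_tsv()
        assert a == b
        c = cm.generate_cohort(cm.CohortConfig(seed=4)).to_tsv()
        assert a != c

    def test_inconsistent_marginals_raise(self):
        with pytest.raises(ValueError, match="sums to"):
            cm.CohortConfig(sex_counts={"F": 20, "M": 20})

    def test_scaled_config_marginals(self):
        config = cm.CohortConfig.scaled(200, seed=1)
        cohort = cm.generate_cohort(config)
        assert len(cohort) == 200
        assert sum(config.diagnosis_counts.values()) == 200
        sub = cm.select_analysis_subset(cohort)
        assert len(sub) == cohort.analysis_eligible_probands


class TestGenerateGenotypes:
    def _sim(self, seed=0, effect=1.5, cf=0.3, n=200, trait="LVWT",
             params=None):
        truth = cm.TruthSet(
            modifiers=[cm.ModifierSpec("MODG1", trait, effect, cf)],
            null_genes=["NULLG1", "NULLG2"],
        )
        cohort = cm.generate_cohort(cm.CohortConfig.scaled(n, seed=seed))
        return cm.generate_genotypes(cohort, truth,
                                     params or cm.SimParams(),
                                     seed=seed), truth

    def test_zero_effect_gives_no_trait_association(self):
        sim, _ = self._sim(seed=5, effect=0.0, n=1000)
        carriers = sim.carrier_status.loc["MODG1"]
        lvwt = sim.cohort.table.set_index("sample_id").lvwt
        r = np.corrcoef(carriers.astype(float),
                        lvwt.loc[carriers.index])[0, 1]
        assert abs(r) < 0.1

    def test_planted_effect_recovered_across_seeds(self):
        """Mean carrier/non-carrier LVWT gap within 0.3 SD of the planted
        +1.5 SD effect, in the vast majority of 100 regenerations."""
        sd = cm.CohortConfig().trait_means_sds["lvwt"][1]
        hits = 0
        for seed in range(100):
            sim, _ = self._sim(seed=seed)
            df = sim.cohort.table.set_index("sample_id")
            carrier = sim.carrier_status.loc["MODG1"]
            diff = df.lvwt[carrier].mean() - df.lvwt[~carrier].mean()
            hits += abs(diff / sd - 1.5) <= 0.3
        assert hits >= 90

    def test_no_missingness_when_rate_zero(self):
        sim, _ = self._sim(params=cm.SimParams(missingness_rate=0.0), n=48)
        G = sim.variants.dosage_matrix()
        assert not np.isnan(G).any()

    def test_unknown_truth_gene_raises(self):
        truth = cm.TruthSet(modifiers=[cm.ModifierSpec("GHOST", "LVWT", 1, 0.2)])
        cohort = cm.generate_cohort(cm.CohortConfig(seed=0))
        models = cm.make_gene_models(["OTHER"])
        with pytest.raises(KeyError, match="GHOST"):
            cm.generate_genotypes(cohort, truth, gene_models=models)

    def test_empty_cohort_raises(self):
        empty = cm.generate_cohort(cm.CohortConfig(
            n_individuals=0, morphology_counts={}, diagnosis_counts={},
            sex_counts={}, ancestry_counts={}))
        with pytest.raises(ValueError):
            cm.generate_genotypes(empty, cm.TruthSet())

    def test_dimensions_and_maf_range(self, small_sim):
        sim, truth, _ = small_sim
        G = sim.variants.dosage_matrix()
        assert G.shape == (48, len(sim.variants))
        lo, hi = cm.SimParams().maf_range
        assert np.all(sim.true_maf >= lo * 0.09)  # CC enrichment may lower
        assert np.all(sim.true_maf <= hi)

    def test_relatives_share_about_half_the_rare_alleles(self):
        rng_hits = []
        for seed in range(20):
            sim, _ = self._sim(seed=seed, n=48)
            df = sim.cohort.table
            G = sim.variants.dosage_matrix()
            idx = {s: i for i, s in enumerate(sim.variants.samples)}
            for row in df[~df.is_proband].itertuples():
                gp = np.nan_to_num(G[idx[row.related_to]])
                gc = np.nan_to_num(G[idx[row.sample_id]])
                carried = gp > 0
                if carried.sum() >= 1:
                    rng_hits.append((gc[carried] > 0).mean())
        assert 0.35 < np.mean(rng_hits) < 0.65


class TestGenerateAnnotations:
    def test_all_novel_when_fraction_one(self, small_sim):
        sim, _, _ = small_sim
        params = cm.SimParams(fraction_novel=1.0, fraction_common=0.0)
        ann = cm.generate_annotations(sim.variants, params, seed=1)
        assert ann.population_af.isna().all()

    def test_reproducible_for_fixed_seed(self, small_sim):
        sim, _, _ = small_sim
        a = cm.generate_annotations(sim.variants, seed=2)
        b = cm.generate_annotations(sim.variants, seed=2)
        assert a.equals(b)

    def test_default_params_cover_every_impact_class(self, small_sim):
        sim, _, _ = small_sim
        ann = cm.generate_annotations(sim.variants, seed=3)
        assert set(ann.impact) == {"HIGH", "MODERATE", "LOW", "MODIFIER"}

    def test_afs_straddle_the_rarity_boundary(self, small_sim):
        sim, _, _ = small_sim
        ann = cm.generate_annotations(sim.variants, seed=4)
        af = ann.population_af
        assert af.isna().any()
        assert (af < 0.01).any() and (af >= 0.01).any()

    def test_favored_keys_guaranteed_functional_and_rare(self, small_sim):
        sim, _, _ = small_sim
        ann = cm.generate_annotations(sim.variants, seed=5,
                                      favored_keys=sim.modifier_keys)
        fav = ann.set_index(["chrom", "pos", "ref", "alt"]).loc[
            [k for k in sim.modifier_keys]]
        assert fav.impact.isin(["HIGH", "MODERATE"]).all()
        assert fav.population_af.isna().all()


class TestGenerateSVCallsets:
    def test_requested_overlap_achieved(self):
        spec = [cm.SVEventSpec("S1", ("delly", "breakdancer"), ro=0.6)]
        sets = cm.generate_sv_callsets(["S1"], spec)
        a, b = sets["delly"][0], sets["breakdancer"][0]
        assert reciprocal_overlap(a, b) == pytest.approx(0.6, abs=0.01)

    def test_identical_intervals_have_overlap_one(self):
        spec = [cm.SVEventSpec("S1", ("delly", "freec"), ro=1.0)]
        sets = cm.generate_sv_callsets(["S1"], spec)
        assert reciprocal_overlap(sets["delly"][0], sets["freec"][0]) == 1.0

    def test_single_caller_event_needs_trusted_caller_downstream(self):
        spec = [cm.SVEventSpec("S1", ("cnvnator",), ro=1.0)]
        sets = cm.generate_sv_callsets(["S1"], spec)
        calls = [c for calls in sets.values() for c in calls]
        assert cm.merge_calls(calls, trusted_caller=None) == []
        spec2 = [cm.SVEventSpec("S1", ("breakseqlite",), ro=1.0)]
        sets2 = cm.generate_sv_callsets(["S1"], spec2)
        calls2 = [c for calls in sets2.values() for c in calls]
        assert len(cm.merge_calls(calls2, trusted_caller="breakseqlite")) == 1

    def test_invalid_overlap_fraction_rejected(self):
        with pytest.raises(ValueError, match="reciprocal overlap"):
            cm.SVEventSpec("S1", ("delly",), ro=1.2)

    def test_default_spec_events_merge_as_designed(self, default_cohort):
        sets = cm.generate_sv_callsets(default_cohort)
        calls = [c for calls in sets.values() for c in calls]
        merged = cm.merge_calls(calls, trusted_caller="breakseqlite")
        rules = {e.rule for e in merged}
        assert rules == {"trusted_caller", "reciprocal_overlap"}


def test_gene_evidence_tables_favor_modifiers():
    truth = cm.TruthSet(
        modifiers=[cm.ModifierSpec("MODG1", "LVWT", 1.5, 0.3)],
        null_genes=["NULLG1", "NULLG2"])
    tabs = cm.generate_gene_evidence_tables(truth, seed=1)
    expr = tabs["expression"].set_index("gene")
    assert expr.loc["MODG1", "rpkm_lv"] > 10
    assert (expr.loc[["NULLG1", "NULLG2"], "rpkm_lv"] < 10).all()
    assert tabs["candidates"] == ["MODG1"]
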