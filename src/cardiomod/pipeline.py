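"""End-to-end discovery run on synthetic data: simulate -> filter -> associate
-> score.

This is the orchestration used by the examples and the reproducibility checks;
each stage is the corresponding module's public API, so any step can be run
in isolation on real inputs instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import filtering, scoring, simulate

__all__ = ["PipelineResult", "default_truth", "run_pipeline"]


def default_truth() -> simulate.TruthSet:
    """Planted architecture mirroring the discovery setting.

    Three modifier genes (wall-thickness, ejection-fraction and case-control
    signals) against a background of null genes; effect sizes follow the
    intermediate-effect regime the rare-variant analysis targets.
    """
    return simulate.TruthSet(
        modifiers=[
            simulate.ModifierSpec("MODG1", "LVWT", 1.5, 0.30),
            simulate.ModifierSpec("MODG2", "EF", -1.5, 0.30),
            simulate.ModifierSpec("MODG3", "CASE_CONTROL", 2.0, 0.30),
        ],
        null_genes=[f"NULLG{i + 1}" for i in range(15)],
    )


@dataclass
class PipelineResult:
    cohort: simulate.Cohort
    analysis_subset: simulate.Cohort
    filter_report: pd.DataFrame
    variant_sets: dict
    association: pd.DataFrame
    scores: pd.DataFrame
    score_summary: pd.DataFrame
    evidence: list = field(default_factory=list)

    def serialize(self) -> str:
        """Canonical text rendering of every tabular output (for determinism
        checks and archival)."""
        parts = [
            "## cohort",
            self.cohort.to_tsv(),
            "## filter_report",
            self.filter_report.to_csv(sep="\t", index=False),
            "## association",
            self.association.to_csv(sep="\t", index=False,
                                    float_format="%.10g"),
            "## scores",
            self.scores.to_csv(sep="\t", index=False, float_format="%.10g"),
            "## summary",
            self.score_summary.to_csv(sep="\t", index=False),
        ]
        return "\n".join(parts)


def run_pipeline(
    seed: int = 0,
    n_individuals: int = 48,
    truth: simulate.TruthSet | None = None,
    params: simulate.SimParams | None = None,
    n_controls: int = 100,
    methods: tuple[str, ...] = ("skat", "skato", "fisher"),
) -> PipelineResult:
    """Run the full candidate-modifier discovery pipeline on synthetic data."""
    truth = truth or default_truth()
    params = params or simulate.SimParams()
    if n_individuals == 48:
        config = simulate.CohortConfig(seed=seed)
    else:
        config = simulate.CohortConfig.scaled(n_individuals, seed=seed)
    ss = np.random.SeedSequence([seed, 7])
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    cohort = simulate.generate_cohort(config)
    gene_models = simulate.make_gene_models(
        truth.modifier_genes + list(truth.null_genes))
    sim = simulate.generate_genotypes(
        cohort, truth, params, gene_models, seed=sub_seeds[0])
    annotations = simulate.generate_annotations(
        sim.variants, params, seed=sub_seeds[1], true_maf=sim.true_maf,
        favored_keys=sim.modifier_keys)
    blacklist = simulate.make_blacklist(gene_models)
    exome = simulate.make_exome_intervals(gene_models)

    fcfg = filtering.FilterConfig()
    sets, report = filtering.run_filter_cascade(
        sim.variants, annotations, blacklist, gene_models, exome, fcfg)

    subset = assoc.select_analysis_subset(sim.cohort)
    data = subset.table.set_index("sample_id")[
        ["lvwt", "ef", "lvotg", "age", "sex", "bmi"]]
    genic = sets["SET2"].subset_samples(subset.samples)
    regions = gene_models.rename(columns={"gene": "region_id"})

    results: list[assoc.GeneTestResult] = []
    for trait_name in ("LVWT", "EF", "LVOTG"):
        trait = assoc.TraitSpec.for_name(trait_name)
        results.extend(assoc.test_regions(genic, regions, trait, data,
                                          methods=methods))

    maf_of_key = {rec.key: maf
                  for rec, maf in zip(sim.variants.records, sim.true_maf)}
    set3_maf = np.array([maf_of_key[rec.key]
                         for rec in sets["SET3"].records])
    controls = simulate.generate_external_controls(
        sets["SET3"], exome.padded(fcfg.exome_pad_bp), n_controls=n_controls,
        true_maf=set3_maf, seed=sub_seeds[2])
    case_exome = sets["SET3"].subset_samples(subset.samples)
    cc_results, _ = assoc.case_control_test(
        case_exome, controls, exome, regions, exome_pad_bp=fcfg.exome_pad_bp,
        methods=methods)
    cc_results = assoc.post_test_gene_filter(cc_results)
    results.extend(cc_results)

    assoc_frame = assoc.results_to_frame(results)
    priors = simulate.generate_gene_evidence_tables(truth, seed=sub_seeds[3])
    evidence = scoring.collect_gene_evidence(
        assoc_frame[~assoc_frame.skipped],
        expression_table=priors["expression"],
        constraint_table=priors["constraint"],
        network_table=priors["network"],
        candidate_list=priors["candidates"],
        flag_list=priors["flags"],
    )
    breakdowns = [scoring.score_gene(ev) for ev in evidence]
    table, summary = scoring.rank_genes(breakdowns)
    return PipelineResult(
        cohort=sim.cohort,
        analysis_subset=subset,
        filter_report=report,
        variant_sets=sets,
        association=assoc_frame,
        scores=table,
        score_summary=summary,
        evidence=evidence,
    )
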