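"""Gene-based rare-variant burden tests on a synthetic cohort.

Tests each gene's rare functional variants against left-ventricular wall
thickness with SKAT (small-sample exact null), SKAT-O and the exact carrier
test after median dichotomization, adjusting for age, sex and BMI.
"""

import pandas as pd

import cardiomod as cm

truth = cm.TruthSet(
    modifiers=[cm.ModifierSpec("MODG1", "LVWT", 1.5, 0.30)],
    null_genes=[f"NULLG{i}" for i in range(1, 9)],
)
cohort = cm.generate_cohort(cm.CohortConfig.scaled(200, seed=3))
gene_models = cm.make_gene_models(truth.modifier_genes + truth.null_genes)
sim = cm.generate_genotypes(cohort, truth, gene_models=gene_models, seed=3)

subset = cm.select_analysis_subset(sim.cohort)
data = subset.table.set_index("sample_id")[["lvwt", "age", "sex", "bmi"]]
table = sim.variants.subset_samples(subset.samples)
regions = gene_models.rename(columns={"gene": "region_id"})

results = cm.test_regions(table, regions, cm.TraitSpec.for_name("LVWT"), data)
frame = cm.results_to_frame(results)
cols = ["region_id", "n_variants", "p_skat", "p_skato", "p_fisher",
        "carriers_high", "carriers_low"]
print(frame[cols].sort_values("p_skat").to_string(index=False))
print("\nMODG1 carries a planted +1.5 SD wall-thickness effect (30% carriers)"
      "\nand should sit far below the null genes; carrier counts show the"
      "\ndirection (more carriers in the thick-walled half of the cohort).")
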