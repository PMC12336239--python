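"""Generate the synthetic sequencing cohort and inspect its structure.

The generator reproduces the study design: 48 individuals in 6 families
(40 unrelated), demographic and cardiac-morphology marginals matched exactly,
and a planted analysis subset of 28 unrelated Caucasian individuals with a
hypertrophic diagnosis.
"""

import cardiomod as cm

cohort = cm.generate_cohort(cm.CohortConfig(seed=1))
df = cohort.table

print(f"individuals: {len(df)}   families with relatives: "
      f"{(df.groupby('family_id').size() > 1).sum()}   "
      f"unrelated: {int(df.is_proband.sum())}")
print("\ndiagnosis counts:")
print(df.diagnosis.value_counts().to_string())
print("\nmorphology percentages (should mirror the cohort table):")
print((100 * df.morphology.value_counts() / len(df)).round(1).to_string())

subset = cm.select_analysis_subset(cohort)
print(f"\nassociation-analysis subset (unrelated, Caucasian, hypertrophic): "
      f"{len(subset)} individuals")
print("-> this is the sample every within-cohort burden test runs on;")
print("   relatives are excluded so no kinship model is needed.")
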