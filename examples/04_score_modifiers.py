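"""End-to-end discovery run: simulate -> filter -> associate -> score.

The 12-point modifier score combines the per-trait minimum burden-test
p-values (LVWT worth 2 points; EF, LVOT gradient and case-control 1 each)
with external priors: cardiac expression > 10 RPKM, LoF/missense constraint
z > 3, coexpression-network Q < 0.01, curated candidate status (+2) and a
-2 penalty for known false-positive-prone genes.
"""

import cardiomod as cm

result = cm.run_pipeline(seed=1)

print("filter cascade:")
print(result.filter_report.to_string(index=False))
print(f"\nanalysis subset: {len(result.analysis_subset)} unrelated "
      "reference-ancestry hypertrophic individuals")
print("\ntop of the ranked modifier table:")
cols = [c for c in result.scores.columns if c != "best_p"]
print(result.scores[cols].head(6).to_string(index=False))
print("\ngenes at or above each score level:")
print(result.score_summary.to_string(index=False))
print("\nMODG1-3 carry planted trait effects plus favorable priors and should"
      "\noutrank every null gene; a null gene can reach ~2 points by chance.")
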