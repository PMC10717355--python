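"""Run the full gene-burden scan on a cohort with planted risk genes.

Per gene: one-sided Fisher tests on carrier counts for the four variant
classes (PTV/MIS/SYN/NON), the combined risk score
2*(-log10 P_PTV) + (-log10 P_MIS), a label-permutation p-value for that
score, Benjamini-Hochberg FDR, and the two selection tiers.  Genes enriched
in synonymous or non-coding variants are background-flagged (likely
confounding) and excluded from selection.
"""

from sgaburden import BurdenConfig, collapse_counts, filter_rare, run_burden_analysis, simulate_cohort
from sgaburden.simulate import scenario_planted_scan

config = scenario_planted_scan(seed=1)  # 12 planted PTV genes + 2 SYN-confounded
data = simulate_cohort(config)

rare = filter_rare(data.variants)  # MAF < 1%; missing frequency counts as rare
matrix = collapse_counts(rare, list(data.samples["sample_id"]),
                         [f"G{i:04d}" for i in range(config.n_genes)])
is_case = (data.samples["group"] == "SGA").to_numpy()

results = run_burden_analysis(matrix, is_case, BurdenConfig(n_permutations=1000, seed=42))

top = results.sort_values("risk_score", ascending=False).head(8)
cols = ["gene", "case_carriers_PTV", "control_carriers_PTV",
        "p_PTV", "p_MIS", "risk_score", "perm_p", "fdr_q", "tier"]
print(top[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))

truth = {g["gene"] for g in data.truth["planted_genes"] if g["variant_type"] == "PTV"}
found = set(results.loc[results["tier"] == "potential_causative", "gene"])
flagged = set(results.loc[results["background_flagged"], "gene"])
print(f"\nplanted risk genes recovered as potential causative: "
      f"{len(found & truth)}/{len(truth)}")
print(f"background-flagged genes: {sorted(flagged)}")
print("\nPlanted genes dominate the risk-score ranking with permutation p at the "
      "1/(B+1) floor; the SYN-planted confounders are caught by the near-neutral "
      "background filter instead of being called causative.")
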