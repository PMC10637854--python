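"""Simulate a cohort and run the full oligogenic risk-score analysis.

Builds a seeded synthetic CN-vs-AD cohort (1000 samples, 200 genes, 10
causal), then runs the whole pipeline: direction-corrected gene
burdens, selection of the genes most correlated with the PET
endophenotypes, logistic risk models for adORS and its comparators,
and held-out evaluation.
"""

import warnings

from adors import SimConfig, analyze_task, simulate_cohort

warnings.filterwarnings("ignore", category=UserWarning)

cohort = simulate_cohort(SimConfig(seed=42))
result = analyze_task(
    cohort.genotypes,
    cohort.sumstats,
    cohort.annotation,
    cohort.phenotypes,
    {"qc": {"enabled": False}, "prs": {"primary_threshold": 0.5}},
)

print(f"selected gene set: {len(result.gene_set.genes)} genes "
      f"(union of top 20 per biomarker)")
causal = set(cohort.truth["causal_genes"])
hit = len(causal & set(result.gene_set.genes))
print(f"planted causal genes recovered: {hit}/{len(causal)}")
print()
print(f"{'model':<18} {'test AUROC':>10} {'test AUPRC':>10} {'staircase':>10}")
for name, report in result.reports.items():
    print(f"{name:<18} {report.test_auroc:>10.3f} {report.test_auprc:>10.3f} "
          f"{result.staircase[name]:>10.2f}")
print()
print("AUROC/AUPRC are measured on the untouched 20% test split; the "
      "staircase statistic (Spearman rho of decile index vs case count, "
      "1.0 = perfectly monotone) shows how well score rank tracks observed "
      "risk. The oligogenic score should beat the PRS comparator here "
      "because the planted signal is concentrated in a few genes.")
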