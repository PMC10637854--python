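"""Exact Shapley contributions for the fitted additive risk model.

For a logistic (additive) model, the Shapley value of each feature has
the closed form beta_j * (x_ij - reference mean), exact on the
log-odds scale — no sampling approximation.  The per-feature mean
|phi| shares show which genes carry the score.
"""

import warnings

from adors import SimConfig, analyze_task, simulate_cohort
from adors.interpret import contributions_long_format

warnings.filterwarnings("ignore", category=UserWarning)

cohort = simulate_cohort(SimConfig(n_samples=800, n_genes=80, n_causal_genes=8, seed=3))
result = analyze_task(
    cohort.genotypes, cohort.sumstats, cohort.annotation, cohort.phenotypes,
    {"qc": {"enabled": False}, "selection": {"k_per_biomarker": 8},
     "prs": {"primary_threshold": 0.5}},
)

contrib = result.contributions["adORS.with.APOE"]
lp = result.models["adORS.with.APOE"].linear_predictor
print(f"attributions for {len(contrib.samples)} samples x "
      f"{len(contrib.features)} features; base value (expected log-odds "
      f"over the training split) = {contrib.base_value:.3f}")

summary = result.contribution_summaries["adORS.with.APOE"]
print("\ncontribution shares (% of total mean |phi|):")
print(summary.head(8).to_string(index=False, float_format="%.2f"))

causal = set(cohort.truth["causal_genes"])
top = [f for f in summary["feature"].head(8) if f in causal]
print(f"\nplanted causal genes among the top contributors: {top}")

long = contributions_long_format(contrib)
print(f"\nlong-format export for beeswarm plotting: {len(long)} rows, "
      f"columns {list(long.columns)}")
print("\nShares sum to 100%; each feature's direction tells whether a "
      "higher burden (or APOE allele score) raises the predicted risk.")
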