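"""Clumping + thresholding PRS and its gene-level contribution split.

Builds the C+T polygenic score: remove the APOE region, greedily clump
(1000-kb window, r^2 > 0.1 absorbed by the stronger signal), keep
variants under the p threshold, and score each sample as the
beta-weighted allele-dosage sum.  Variant contributions beta_k * x_ik
are then pooled per gene, which partitions the score exactly.
"""

import numpy as np

from adors import SimConfig, simulate_cohort
from adors.burden import assign_variants_to_genes
from adors.interpret import prs_gene_contribution, summarize_contributions
from adors.prs import ClumpConfig, build_prs_model, prs_score

cohort = simulate_cohort(SimConfig(n_samples=800, n_genes=60, n_causal_genes=6, seed=11))

# at this simulated-GWAS scale use the lenient end of the threshold grid
cfg = ClumpConfig(primary_threshold=0.1)
model = build_prs_model(cohort.sumstats, cohort.genotypes, cfg)
print(f"{len(cohort.sumstats)} summary-stats variants -> "
      f"{len(model.variants)} retained after APOE removal, clumping "
      f"(window {cfg.window_kb} kb, r2 > {cfg.r2_max}), p <= {cfg.primary_threshold}")

scores = prs_score(model, cohort.genotypes)
print(f"PRS over {len(scores)} samples: "
      f"mean {scores['score'].mean():.3f}, sd {scores['score'].std():.3f}")

gene_map, _ = assign_variants_to_genes(cohort.genotypes, cohort.annotation)
contrib = prs_gene_contribution(model, cohort.genotypes, gene_map)
total = scores.set_index("sample")["score"].to_numpy()
gap = np.abs(contrib.values.sum(axis=1) - total).max()
print(f"gene buckets reproduce the score exactly "
      f"(max |bucket sum - PRS| = {gap:.2e})")

summary = summarize_contributions(contrib)
print("\ntop gene contributions (% of mean |contribution|):")
print(summary.head(5).to_string(index=False, float_format="%.2f"))
print("\nA positive direction means higher effect-allele load in that gene "
      "pushes the score up; the intergenic bucket pools variants outside "
      "every annotated gene.")
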