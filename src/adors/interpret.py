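"""Gene-level contribution decomposition.

For an additive (logistic) model the Shapley value of feature j for
sample i has a closed form on the linear-predictor scale:

    phi_ij = beta_j * (x_ij - mean_ref(x_j))

with the reference mean taken over a background set (the training
split by default).  This is exact — identical to full coalition
enumeration under a mean-substitution value function — so no sampling
approximation is involved.  For the PRS comparator, variant-level
contributions beta_k * x_ik are summed within each gene (intergenic
variants pool into a pseudo-gene), which conserves the total score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix
from .models import RiskModel
from .prs import PRSModel

__all__ = [
    "ContributionMatrix",
    "shap_additive",
    "prs_gene_contribution",
    "summarize_contributions",
    "contributions_long_format",
]

INTERGENIC = "intergenic"


@dataclass
class ContributionMatrix:
    """Per-sample, per-feature attributions plus the base value.

    ``base_value`` is the expected linear predictor over the reference
    set; for every sample base_value + sum_j phi_ij equals the model's
    linear predictor (local accuracy).
    """

    samples: list[str]
    features: list[str]
    values: np.ndarray
    base_value: float
    feature_values: np.ndarray | None = None  # raw inputs, for beeswarm export

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError("contribution matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.features)

    def totals(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1)


def shap_additive(
    model: RiskModel,
    features: pd.DataFrame,
    reference: pd.DataFrame | None = None,
) -> ContributionMatrix:
    """Exact Shapley attributions for an additive risk model.

    ``features`` must contain every weighted feature (gene burdens and
    covariates); ``reference`` defaults to the training-split rows of
    ``features`` recorded in the model, falling back to all rows.
    Attributions are on the linear-predictor (log-odds) scale.
    """
    weights = {**model.gene_weights, **model.covariate_weights}
    names = list(weights)
    missing = [n for n in names if n not in features.columns]
    if missing:
        raise KeyError(f"features lack model columns: {missing}")
    if reference is None:
        train = [s for s in model.train_samples if s in features.index]
        reference = features.loc[train] if train else features
    ref_missing = [n for n in names if n not in reference.columns]
    if ref_missing:
        raise KeyError(f"reference lacks model columns: {ref_missing}")
    if len(reference) == 0:
        raise ValueError("reference set is empty")
    beta = np.array([weights[n] for n in names])
    ref_mean = reference[names].to_numpy(dtype=float).mean(axis=0)
    x = features[names].to_numpy(dtype=float)
    phi = beta[None, :] * (x - ref_mean[None, :])
    base = float(model.intercept + beta @ ref_mean)
    return ContributionMatrix(
        samples=[str(s) for s in features.index],
        features=names,
        values=phi,
        base_value=base,
        feature_values=x,
    )


def prs_gene_contribution(
    prs_model: PRSModel,
    geno: GenotypeMatrix,
    gene_map: dict[str, list[int]],
    train_samples: list[str] | None = None,
) -> ContributionMatrix:
    """Gene-level PRS contributions c_ij = sum_{k in g_j} beta_k x_ik.

    Only retained PRS variants contribute; variants of no gene pool
    into the ``intergenic`` bucket.  Bucket sums reproduce the PRS
    score exactly.  Missing dosages are mean-imputed over
    ``train_samples`` (consistent with :func:`adors.prs.prs_score`).
    """
    col_of = {v.vid: i for i, v in enumerate(geno.variants)}
    retained = [s for s in prs_model.snp_ids if s in col_of]
    beta_of = dict(zip(prs_model.variants["SNP"].astype(str), prs_model.variants["BETA"]))
    cols = np.array([col_of[s] for s in retained], dtype=int)
    d = geno.dosage[:, cols]
    if train_samples is None:
        train_mask = np.ones(len(geno.samples), dtype=bool)
    else:
        tset = set(train_samples)
        train_mask = np.array([s in tset for s in geno.samples])
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(train_mask[:, None], d, np.nan), axis=0)
    d = np.where(np.isnan(d), np.nan_to_num(means, nan=0.0)[None, :], d)
    beta = np.array([beta_of[s] for s in retained])
    weighted = d * beta[None, :]  # per-variant contributions

    # each retained variant lands in exactly one bucket (its first
    # containing gene in sorted order) so buckets partition the score
    pos_in_retained = {col_of[s]: k for k, s in enumerate(retained)}
    assigned = np.zeros(len(retained), dtype=bool)
    genes, bucket_cols, bucket_doses = [], [], []
    for gene in sorted(gene_map):
        idx = [
            pos_in_retained[j]
            for j in gene_map[gene]
            if j in pos_in_retained and not assigned[pos_in_retained[j]]
        ]
        if not idx:
            continue
        genes.append(gene)
        bucket_cols.append(weighted[:, idx].sum(axis=1))
        bucket_doses.append(d[:, idx].sum(axis=1))
        assigned[idx] = True
    leftover = np.flatnonzero(~assigned)
    if leftover.size:
        genes.append(INTERGENIC)
        bucket_cols.append(weighted[:, leftover].sum(axis=1))
        bucket_doses.append(d[:, leftover].sum(axis=1))
    values = np.column_stack(bucket_cols) if bucket_cols else np.empty((len(geno.samples), 0))
    doses = np.column_stack(bucket_doses) if bucket_doses else np.empty((len(geno.samples), 0))
    return ContributionMatrix(
        samples=list(geno.samples),
        features=genes,
        values=values,
        base_value=0.0,
        feature_values=doses,  # plain allele-count sums, for the beeswarm colouring
    )


def summarize_contributions(contrib: ContributionMatrix) -> pd.DataFrame:
    """Mean-|phi| percentage share and direction of effect per feature.

    share_pct_j = mean_i |phi_ij| / sum_j mean_i |phi_ij| * 100 (sums
    to 100); direction is the sign of the correlation between a
    feature's raw value and its attribution (+1 risk-increasing with
    the feature, -1 protective, 0 undetermined).
    """
    mean_abs = np.abs(contrib.values).mean(axis=0)
    total = mean_abs.sum()
    if total == 0:
        raise ValueError("all contributions are zero; shares undefined")
    shares = mean_abs / total * 100.0
    directions = []
    for j in range(len(contrib.features)):
        phi = contrib.values[:, j]
        x = contrib.feature_values[:, j] if contrib.feature_values is not None else None
        if x is None or np.ptp(x) == 0 or np.ptp(phi) == 0:
            directions.append(0)
        else:
            directions.append(int(np.sign(np.corrcoef(x, phi)[0, 1])))
    return pd.DataFrame(
        {"feature": contrib.features, "share_pct": shares, "direction": directions}
    ).sort_values("share_pct", ascending=False, kind="mergesort").reset_index(drop=True)


def contributions_long_format(contrib: ContributionMatrix) -> pd.DataFrame:
    """Long-format export (sample, feature, value, attribution) for plotting."""
    rows = []
    for i, s in enumerate(contrib.samples):
        for j, f in enumerate(contrib.features):
            rows.append(
                {
                    "sample": s,
                    "feature": f,
                    "value": (
                        contrib.feature_values[i, j]
                        if contrib.feature_values is not None
                        else np.nan
                    ),
                    "attribution": contrib.values[i, j],
                }
            )
    return pd.DataFrame(rows)
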