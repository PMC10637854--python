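"""Endophenotype-guided gene selection.

Gene burdens are ranked by their Pearson correlation with each
neuroimaging biomarker (FDG-PET and AV45-PET SUVR by default) and the
top k genes per biomarker are pooled.  The union — typically smaller
than k times the number of biomarkers because of overlap — is the
condensed gene set entering the oligogenic risk model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .burden import BurdenMatrix

__all__ = ["SelectionConfig", "GeneSet", "pearson_r", "select_genes", "ConstantInputError"]


class ConstantInputError(ValueError):
    """Correlation requested against a constant vector."""


@dataclass(frozen=True)
class SelectionConfig:
    """How the oligogenic gene set is chosen.

    k_per_biomarker : genes taken per biomarker (default 20).
    biomarkers : phenotype columns used as endophenotypes.
    correlation_scope : 'train_only' computes correlations on the
        training split only (no selection leakage into held-out
        evaluation); 'full_cohort' uses every sample.
    ranking : 'absolute_r' ranks by |r|, 'signed_r' by r descending.
    """

    k_per_biomarker: int = 20
    biomarkers: tuple[str, ...] = ("fdg_suvr", "av45_suvr")
    correlation_scope: str = "train_only"
    ranking: str = "absolute_r"

    def __post_init__(self) -> None:
        if self.k_per_biomarker < 1:
            raise ValueError("k_per_biomarker must be >= 1")
        if not self.biomarkers:
            raise ValueError("at least one biomarker required")
        if self.correlation_scope not in ("train_only", "full_cohort"):
            raise ValueError("correlation_scope must be train_only or full_cohort")
        if self.ranking not in ("absolute_r", "signed_r"):
            raise ValueError("ranking must be absolute_r or signed_r")


@dataclass
class GeneSet:
    """Selected genes with per-biomarker provenance."""

    genes: list[str]  # union, sorted
    per_biomarker: pd.DataFrame  # columns: biomarker, rank, gene, r

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def pearson_r(x, y) -> float:
    """Pearson correlation on pairwise-complete observations.

    Raises :class:`ConstantInputError` (rather than returning 0) when
    either vector is constant after dropping incomplete pairs, and
    ValueError with fewer than 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def select_genes(
    burdens: BurdenMatrix,
    phenotypes: pd.DataFrame,
    config: SelectionConfig | None = None,
    train_ids: list[str] | None = None,
) -> GeneSet:
    """Rank genes by burden-biomarker correlation and pool the top k.

    ``phenotypes`` is indexed by sample and must contain the configured
    biomarker columns.  Genes with an undefined correlation (constant
    burden) are ineligible.  Ties in the ranking statistic are broken
    lexicographically by gene symbol; if fewer eligible genes than k
    exist, all are returned with a warning.
    """
    cfg = config or SelectionConfig()
    bdf = burdens.to_frame()
    if cfg.correlation_scope == "train_only":
        if train_ids is None:
            raise ValueError("train_ids required with correlation_scope='train_only'")
        missing = set(train_ids) - set(bdf.index)
        if missing:
            raise ValueError(f"train ids absent from burden matrix: {sorted(missing)[:5]}")
        scope = list(train_ids)
    else:
        scope = list(bdf.index)
    bdf = bdf.loc[scope]
    pheno = phenotypes.loc[scope]

    rows = []
    for biomarker in cfg.biomarkers:
        if biomarker not in pheno.columns:
            raise KeyError(f"biomarker column {biomarker!r} not in phenotype table")
        y = pheno[biomarker].to_numpy(dtype=float)
        stats_per_gene = []
        for gene in bdf.columns:
            try:
                r = pearson_r(bdf[gene].to_numpy(), y)
            except (ConstantInputError, ValueError):
                continue
            key = abs(r) if cfg.ranking == "absolute_r" else r
            stats_per_gene.append((gene, r, key))
        # descending by ranking statistic, ties lexicographic by symbol
        stats_per_gene.sort(key=lambda t: (-t[2], t[0]))
        if len(stats_per_gene) < cfg.k_per_biomarker:
            import warnings

            warnings.warn(
                f"only {len(stats_per_gene)} eligible genes for {biomarker}; "
                f"requested {cfg.k_per_biomarker}"
            )
        for rank, (gene, r, _) in enumerate(stats_per_gene[: cfg.k_per_biomarker], 1):
            rows.append({"biomarker": biomarker, "rank": rank, "gene": gene, "r": r})
    per_biomarker = pd.DataFrame(rows, columns=["biomarker", "rank", "gene", "r"])
    union = sorted(set(per_biomarker["gene"]))
    return GeneSet(genes=union, per_biomarker=per_biomarker)
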