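"""Direction-aware collapse of variant dosages into gene burdens.

Each variant carries an association direction taken from the sign of
its GWAS log-odds effect.  Risk-increasing variants contribute their
effect-allele count x; protective variants contribute the complement
2 - x, so that effects accumulate within a gene instead of cancelling.
The burden of gene j for sample i is the sum of these transformed
dosages over the variants falling in the gene's interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, normalize_chrom

__all__ = [
    "direction_map",
    "assign_variants_to_genes",
    "transform_dosage",
    "compute_burdens",
    "BurdenMatrix",
]


@dataclass
class BurdenMatrix:
    """Sample x gene burden values with per-gene variant counts."""

    samples: list[str]
    genes: list[str]
    values: np.ndarray
    variant_counts: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError("burden matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variant_counts: dict[str, int] | None = None) -> "BurdenMatrix":
        return cls(
            samples=[str(s) for s in df.index],
            genes=[str(g) for g in df.columns],
            values=df.to_numpy(dtype=float),
            variant_counts=variant_counts or {g: 0 for g in df.columns},
        )


def direction_map(sumstats: pd.DataFrame) -> dict[str, int]:
    """Per-variant direction from the sign of BETA: -1 protective, +1 otherwise.

    A zero effect takes the identity (+1) branch.
    """
    return {
        str(snp): (-1 if beta < 0 else 1)
        for snp, beta in zip(sumstats["SNP"], sumstats["BETA"])
    }


def assign_variants_to_genes(
    geno: GenotypeMatrix, annotation: pd.DataFrame
) -> tuple[dict[str, list[int]], list[int]]:
    """Map gene -> variant column indices by interval containment.

    ``annotation`` has columns (gene, chrom, start, end) in 0-based
    half-open coordinates.  A variant belongs to every gene whose
    interval contains it (overlapping genes multi-assign); variants in
    no gene are returned as the intergenic index list.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for row in annotation.itertuples(index=False):
        by_chrom.setdefault(normalize_chrom(row.chrom), []).append(
            (int(row.start), int(row.end), str(row.gene))
        )
    gene_map: dict[str, list[int]] = {str(g): [] for g in annotation["gene"]}
    intergenic: list[int] = []
    for j, v in enumerate(geno.variants):
        hit = False
        for start, end, gene in by_chrom.get(v.chrom, ()):
            if start <= v.pos - 1 < end:
                gene_map[gene].append(j)
                hit = True
        if not hit:
            intergenic.append(j)
    return gene_map, intergenic


def transform_dosage(x: float, direction: int) -> float:
    """Direction-corrected dosage: 2 - x for protective variants, x otherwise."""
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 (negative) or +1 (positive)")
    if np.isnan(x):
        raise ValueError("missing dosage must be resolved by the imputation policy")
    return 2.0 - x if direction == -1 else float(x)


def compute_burdens(
    geno: GenotypeMatrix,
    directions: dict[str, int],
    gene_map: dict[str, list[int]],
    missing_policy: str = "mean",
    train_samples: list[str] | None = None,
) -> BurdenMatrix:
    """Collapse direction-corrected dosages into per-gene burdens.

    Only variants with a known direction enter a burden (a direction
    requires a GWAS sign).  Missing dosages are imputed with the
    per-variant mean over ``train_samples`` (default: all samples)
    under ``missing_policy="mean"``; under ``"drop"`` a cell with any
    missing constituent dosage becomes NaN.  Genes with zero usable
    variants are excluded.
    """
    if missing_policy not in ("mean", "drop"):
        raise ValueError("missing_policy must be 'mean' or 'drop'")
    d = geno.dosage
    vids = [v.vid for v in geno.variants]
    dir_vec = np.array([directions.get(vid, 0) for vid in vids], dtype=float)

    if missing_policy == "mean":
        if train_samples is None:
            train_mask = np.ones(len(geno.samples), dtype=bool)
        else:
            train_set = set(train_samples)
            train_mask = np.array([s in train_set for s in geno.samples])
            if not train_mask.any():
                raise ValueError("no training samples present in genotype matrix")
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(np.where(train_mask[:, None], d, np.nan), axis=0)
        col_means = np.nan_to_num(col_means, nan=0.0)
        d = np.where(np.isnan(d), col_means[None, :], d)

    s = np.where(dir_vec[None, :] < 0, 2.0 - d, d)

    genes: list[str] = []
    cols: list[np.ndarray] = []
    counts: dict[str, int] = {}
    for gene in sorted(gene_map):
        idx = [j for j in gene_map[gene] if dir_vec[j] != 0]
        if not idx:
            continue
        genes.append(gene)
        counts[gene] = len(idx)
        cols.append(s[:, idx].sum(axis=1))
    values = np.column_stack(cols) if cols else np.empty((len(geno.samples), 0))
    return BurdenMatrix(
        samples=list(geno.samples), genes=genes, values=values, variant_counts=counts
    )
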