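"""Clumping + thresholding polygenic risk score comparator.

The C+T construction: remove the APOE region, greedily clump variants
(ascending GWAS p; an index variant absorbs every variant on the same
chromosome within the window whose squared dosage correlation exceeds
r2_max, estimated on the analysis cohort itself), then keep variants
passing the p-value threshold.  The score is the beta-weighted sum of
effect-allele dosages over the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import APOE_REGION, GenomicInterval, GenotypeMatrix

__all__ = ["ClumpConfig", "PRSModel", "clump", "prs_score", "build_prs_model"]


@dataclass(frozen=True)
class ClumpConfig:
    """C+T parameters (PLINK-style defaults used in AD PRS practice)."""

    window_kb: int = 1000
    r2_max: float = 0.1
    p_thresholds: tuple[float, ...] = (5e-8, 1e-5, 0.1, 0.5)
    primary_threshold: float = 1e-5
    apoe_region: GenomicInterval = APOE_REGION

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_max < 1.0:
            raise ValueError("r2_max must be in (0, 1)")
        for t in (*self.p_thresholds, self.primary_threshold):
            if not 0.0 < t <= 1.0:
                raise ValueError("p thresholds must lie in (0, 1]")


@dataclass
class PRSModel:
    """Retained variant weights after clumping and thresholding."""

    variants: pd.DataFrame  # columns: SNP, CHR, BP, A1, BETA, P
    threshold: float
    clump_provenance: dict[str, str] = field(default_factory=dict)  # removed -> index

    @property
    def snp_ids(self) -> list[str]:
        return [str(s) for s in self.variants["SNP"]]


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation on pairwise-complete dosages."""
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        return 0.0
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    sumstats: pd.DataFrame,
    geno: GenotypeMatrix,
    config: ClumpConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Greedy LD clumping of summary statistics against cohort genotypes.

    Variants inside the APOE region are removed before clumping.
    Candidates absent from the genotype matrix cannot contribute an
    r^2 estimate and are dropped with a warning.  Ties on p are broken
    by (chrom, pos) for determinism.

    Returns the retained summary-statistics rows (index-variant set,
    sorted by p then coordinate) and a provenance map
    removed SNP -> absorbing index SNP.
    """
    cfg = config or ClumpConfig()
    window_bp = cfg.window_kb * 1000
    dosage_col = {v.vid: i for i, v in enumerate(geno.variants)}

    ss = sumstats.copy()
    in_apoe = [
        cfg.apoe_region.contains_pos(c, int(b)) for c, b in zip(ss["CHR"], ss["BP"])
    ]
    ss = ss[~np.asarray(in_apoe)]
    present = ss["SNP"].astype(str).isin(dosage_col.keys())
    if (~present).any():
        import warnings

        warnings.warn(f"{int((~present).sum())} summary-stats variants absent from genotypes; dropped")
        ss = ss[present]
    ss = ss.sort_values(["P", "CHR", "BP"], kind="mergesort").reset_index(drop=True)

    claimed = np.zeros(len(ss), dtype=bool)
    retained = np.zeros(len(ss), dtype=bool)
    provenance: dict[str, str] = {}
    chrom = ss["CHR"].astype(str).to_numpy()
    bp = ss["BP"].astype(int).to_numpy()
    snp = ss["SNP"].astype(str).to_numpy()
    for i in range(len(ss)):
        if claimed[i]:
            continue
        claimed[i] = True
        retained[i] = True
        x_i = geno.dosage[:, dosage_col[snp[i]]]
        near = np.flatnonzero(
            (~claimed) & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window_bp)
        )
        for j in near:
            if _pairwise_r2(x_i, geno.dosage[:, dosage_col[snp[j]]]) > cfg.r2_max:
                claimed[j] = True
                provenance[snp[j]] = snp[i]
    return ss[retained].reset_index(drop=True), provenance


def build_prs_model(
    sumstats: pd.DataFrame,
    geno: GenotypeMatrix,
    config: ClumpConfig | None = None,
    threshold: float | None = None,
) -> PRSModel:
    """APOE-region removal -> clumping -> p-thresholding, in that order."""
    cfg = config or ClumpConfig()
    thr = cfg.primary_threshold if threshold is None else threshold
    clumped, provenance = clump(sumstats, geno, cfg)
    kept = clumped[clumped["P"] <= thr].reset_index(drop=True)
    cols = ["SNP", "CHR", "BP", "A1", "BETA", "P"]
    return PRSModel(variants=kept[cols], threshold=thr, clump_provenance=provenance)


def prs_score(
    model: PRSModel,
    geno: GenotypeMatrix,
    train_samples: list[str] | None = None,
    model_name: str = "PRS",
    task: str = "",
) -> pd.DataFrame:
    """Weighted allele-dosage sum over the retained variants.

    Assumes dosages already aligned to the summary-statistics effect
    allele.  Missing dosages are imputed with the per-variant mean over
    ``train_samples`` (default: all samples), sharing the burden
    module's policy.
    """
    if model.variants.empty:
        raise ValueError("PRS model retains no variants")
    col_of = {v.vid: i for i, v in enumerate(geno.variants)}
    missing = [s for s in model.snp_ids if s not in col_of]
    if missing:
        raise KeyError(f"genotypes lack PRS variants: {missing[:5]}")
    cols = [col_of[s] for s in model.snp_ids]
    d = geno.dosage[:, cols]
    if train_samples is None:
        train_mask = np.ones(len(geno.samples), dtype=bool)
    else:
        tset = set(train_samples)
        train_mask = np.array([s in tset for s in geno.samples])
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(train_mask[:, None], d, np.nan), axis=0)
    d = np.where(np.isnan(d), np.nan_to_num(means, nan=0.0)[None, :], d)
    beta = model.variants["BETA"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "sample": list(geno.samples),
            "score": d @ beta,
            "model_name": model_name,
            "task": task,
        }
    )
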