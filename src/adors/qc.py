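"""Variant-level quality control.

Filters follow the standard WGS pre-processing order used for common
variant analyses: mask low-confidence genotype calls (GQ/DP), then drop
variants by missing rate, monomorphism, and departure from
Hardy-Weinberg equilibrium (exact test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "filter_variants",
    "mask_low_quality_calls",
]


@dataclass(frozen=True)
class QCThresholds:
    """Variant QC thresholds.

    ``max_missing_rate``: variants with a strictly greater fraction of
    missing calls are removed.  ``hwe_alpha``: variants with exact HWE
    p strictly below this are removed.  ``gq_min``/``dp_min``: calls
    with GQ or DP strictly below these become missing (when the VCF
    carries the fields).
    """

    max_missing_rate: float = 0.20
    hwe_alpha: float = 1e-6
    gq_min: int = 20
    dp_min: int = 10
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must be in (0, 1)")


@dataclass
class QCReport:
    """Per-rule removal counts plus a per-variant pass/fail table."""

    n_input: int
    n_removed_missing: int
    n_removed_monomorphic: int
    n_removed_hwe: int
    per_variant: pd.DataFrame  # columns: vid, missing_rate, hwe_p, fail_rule

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_removed_missing
            - self.n_removed_monomorphic
            - self.n_removed_hwe
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["missingness", "monomorphic", "hwe"],
                "n_removed": [
                    self.n_removed_missing,
                    self.n_removed_monomorphic,
                    self.n_removed_hwe,
                ],
            }
        )


def hwe_heterozygote_distribution(n_het: int, n_hom_1: int, n_hom_2: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count.

    Given observed genotype counts, conditions on the total sample size
    and the minor-allele count and returns ``(het_values, probs)`` over
    every feasible heterozygote count (same parity as the allele count).
    """
    n = n_het + n_hom_1 + n_hom_2
    n_rare = 2 * min(n_hom_1, n_hom_2) + n_het  # minor allele count
    # feasible het counts share the parity of the minor allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(het | n, n_rare) up to a constant: multinomial over genotypes
    # times 2^het, from the permanental form of the conditional law.
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Sums, over the conditional distribution of the heterozygote count
    given the allele counts, the probabilities of all tables no more
    likely than the observed one.  Monomorphic input has a single
    feasible table and returns 1.0.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    if n_hom_ref + n_het + n_hom_alt == 0:
        raise ValueError("no genotypes observed")
    hets, probs = hwe_heterozygote_distribution(n_het, n_hom_ref, n_hom_alt)
    p_obs = probs[hets == n_het][0]
    # small relative slack so ties count as ties despite float rounding
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def mask_low_quality_calls(
    geno: GenotypeMatrix, gq_min: int = 20, dp_min: int = 10
) -> GenotypeMatrix:
    """Set calls with GQ < gq_min or DP < dp_min to missing.

    A no-op (with a warning) when the matrix carries no per-call
    quality fields, e.g. when it came from a dosage TSV.
    """
    if geno.gq is None and geno.dp is None:
        import warnings

        warnings.warn("no GQ/DP fields present; quality masking skipped")
        return geno
    dosage = geno.dosage.copy()
    if geno.gq is not None:
        dosage[np.nan_to_num(geno.gq, nan=np.inf) < gq_min] = np.nan
    if geno.dp is not None:
        dosage[np.nan_to_num(geno.dp, nan=np.inf) < dp_min] = np.nan
    return GenotypeMatrix(
        samples=list(geno.samples),
        variants=list(geno.variants),
        dosage=dosage,
        gq=geno.gq,
        dp=geno.dp,
        n_multiallelic_dropped=geno.n_multiallelic_dropped,
        n_masked_region=geno.n_masked_region,
    )


def filter_variants(
    geno: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants failing missingness, monomorphism, or HWE.

    Rules are applied in that order and each variant is charged to the
    first rule it fails.  When quality fields are present, calls are
    masked by GQ/DP before the missing rate is computed.
    """
    thr = thresholds or QCThresholds()
    if geno.gq is not None or geno.dp is not None:
        geno = mask_low_quality_calls(geno, thr.gq_min, thr.dp_min)
    d = geno.dosage
    n = d.shape[0]
    missing_rate = np.isnan(d).mean(axis=0)

    fail_rule = np.array([""] * geno.n_variants, dtype=object)
    hwe_p = np.full(geno.n_variants, np.nan)
    for j in range(geno.n_variants):
        if missing_rate[j] > thr.max_missing_rate:
            fail_rule[j] = "missingness"
            continue
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0 or (thr.drop_monomorphic and np.all(col == col[0])):
            fail_rule[j] = "monomorphic"
            continue
        counts = [int((col == g).sum()) for g in (0.0, 1.0, 2.0)]
        hwe_p[j] = hwe_exact_test(*counts)
        if hwe_p[j] < thr.hwe_alpha:
            fail_rule[j] = "hwe"

    report = QCReport(
        n_input=geno.n_variants,
        n_removed_missing=int((fail_rule == "missingness").sum()),
        n_removed_monomorphic=int((fail_rule == "monomorphic").sum()),
        n_removed_hwe=int((fail_rule == "hwe").sum()),
        per_variant=pd.DataFrame(
            {
                "vid": [v.vid for v in geno.variants],
                "missing_rate": missing_rate,
                "hwe_p": hwe_p,
                "fail_rule": fail_rule,
            }
        ),
    )
    keep = np.flatnonzero(fail_rule == "")
    return geno.subset_variants(keep), report
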