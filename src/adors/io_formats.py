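"""Readers, writers and in-memory containers for the external artifacts.

Coordinate conventions
----------------------
Every input format keeps its native convention at the file boundary
(VCF and refGene intervals are 1-based inclusive, BED is 0-based
half-open) and everything in memory is 0-based half-open.  A variant at
VCF position ``pos`` therefore falls inside a stored interval
``[start, end)`` iff ``start <= pos - 1 < end``.

Dosages are counted on the *effect* allele of each variant (the ALT
allele straight after reading; possibly the REF allele after
:func:`align_alleles`).  Missing genotypes are carried as ``NaN`` in a
float matrix — downstream policies decide imputation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "GenomicInterval",
    "FormatError",
    "EmptyResultError",
    "read_genotypes",
    "read_dosage_tsv",
    "read_summary_stats",
    "read_gene_annotation",
    "read_phenotypes",
    "align_alleles",
    "write_scores",
    "read_scores",
    "parse_region",
    "normalize_chrom",
    "APOE_REGION",
]

SUMSTATS_COLUMNS = ["CHR", "BP", "SNP", "A1", "A2", "BETA", "P"]

#: Cognitive assessments carried in the phenotype table.
COGNITIVE_SCORES = ["ADAS13", "CDRSB", "FAQ", "MMSE", "RAVLT"]

#: Diagnosis tokens allowed in a longitudinal visit sequence.
DIAGNOSES = ("CN", "EMCI", "LMCI", "AD")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class EmptyResultError(ValueError):
    """An operation produced zero records where at least one is required."""


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label to the bare form (``chr19`` -> ``19``)."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def contains_pos(self, chrom: str, pos_1based: int) -> bool:
        return (
            normalize_chrom(chrom) == self.chrom
            and self.start <= pos_1based - 1 < self.end
        )


def parse_region(region: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` given in 1-based inclusive coordinates."""
    m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", region.strip())
    if m is None:
        raise FormatError(f"cannot parse region {region!r}; expected chrom:start-end")
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    return GenomicInterval(m.group(1), start - 1, end)


#: The APOE locus (GRCh38), stored 0-based half-open; excluded from PRS
#: and from the oligogenic gene set.
APOE_REGION = parse_region("chr19:44000000-46000000")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with an explicit effect allele."""

    chrom: str
    pos: int  # 1-based, as printed in VCF
    vid: str
    ref_allele: str
    alt_allele: str
    effect_allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.effect_allele not in (self.ref_allele, self.alt_allele):
            raise ValueError(
                f"effect allele {self.effect_allele!r} of {self.vid} is neither "
                f"ref {self.ref_allele!r} nor alt {self.alt_allele!r}"
            )


@dataclass
class GenotypeMatrix:
    """Sample x variant effect-allele dosages with variant metadata.

    ``dosage`` is a float array; non-missing entries are in {0, 1, 2} and
    missing calls are ``NaN``.  Optional per-call ``gq``/``dp`` arrays are
    retained from VCF input so quality masking can run downstream.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    n_multiallelic_dropped: int = 0
    n_masked_region: int = 0

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be in {0, 1, 2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_frame(self) -> pd.DataFrame:
        """Variant metadata as a DataFrame (one row per variant, in order)."""
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "vid": [v.vid for v in self.variants],
                "ref": [v.ref_allele for v in self.variants],
                "alt": [v.alt_allele for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
            }
        )

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """A copy restricted to the variants at positional ``index``."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in index],
            dosage=self.dosage[:, index].copy(),
            gq=None if self.gq is None else self.gq[:, index].copy(),
            dp=None if self.dp is None else self.dp[:, index].copy(),
            n_multiallelic_dropped=self.n_multiallelic_dropped,
            n_masked_region=self.n_masked_region,
        )


def read_genotypes(path, region_mask: str | GenomicInterval | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF (by extension) or a dosage TSV.

    Multi-allelic VCF records are dropped and counted in
    ``n_multiallelic_dropped``; variants inside ``region_mask`` are
    excluded and counted in ``n_masked_region``.  Dosages count the ALT
    allele.  Raises :class:`EmptyResultError` if nothing survives.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".vcf.bgz")):
        geno = _read_vcf(path)
    else:
        geno = read_dosage_tsv(path)
    if region_mask is not None:
        if isinstance(region_mask, str):
            region_mask = parse_region(region_mask)
        keep = [
            i
            for i, v in enumerate(geno.variants)
            if not region_mask.contains_pos(v.chrom, v.pos)
        ]
        n_masked = geno.n_variants - len(keep)
        geno = geno.subset_variants(np.asarray(keep, dtype=int))
        geno.n_masked_region = n_masked
    if geno.n_variants == 0:
        raise EmptyResultError("no variants remain after reading/masking")
    return geno


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    dp_cols: list[np.ndarray] = []
    have_gq = have_dp = True
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        variants.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                vid=rec.ID or f"{normalize_chrom(rec.CHROM)}:{rec.POS}",
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                effect_allele=rec.ALT[0],
            )
        )
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = rec.gt_types.astype(float)
        col = np.where(gt == 3, 2.0, gt)
        col[gt == 2] = np.nan
        dosage_cols.append(col)
        if have_gq:
            try:
                gq = rec.format("GQ")
                assert gq is not None
                gq_cols.append(gq[:, 0].astype(float))
            except Exception:
                have_gq = False
        if have_dp:
            try:
                dp = rec.format("DP")
                assert dp is not None
                dp_cols.append(dp[:, 0].astype(float))
            except Exception:
                have_dp = False
    dosage = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    )
    gq_arr = np.column_stack(gq_cols) if have_gq and len(gq_cols) == len(variants) else None
    dp_arr = np.column_stack(dp_cols) if have_dp and len(dp_cols) == len(variants) else None
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosage=dosage,
        gq=gq_arr,
        dp=dp_arr,
        n_multiallelic_dropped=n_multi,
    )


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    """Read a sample x variant dosage matrix.

    First column is the sample ID; remaining column headers are variant
    IDs of the form ``chrom:pos:ref:alt`` (effect allele = alt).  Plain
    variant IDs without coordinates are accepted but then no positional
    operations (region masks, gene assignment, clumping) are possible.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError("dosage TSV needs a sample column plus >=1 variant column")
    samples = df.iloc[:, 0].tolist()
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample IDs in dosage TSV")
    variants = []
    for col in df.columns[1:]:
        parts = str(col).split(":")
        if len(parts) == 4:
            chrom, pos, ref, alt = parts
            variants.append(
                VariantRecord(chrom, int(pos), col, ref, alt, effect_allele=alt)
            )
        else:
            variants.append(VariantRecord("0", 0, col, "N", "A", effect_allele="A"))
    dosage = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def read_summary_stats(path) -> pd.DataFrame:
    """Read GWAS summary statistics (columns CHR, BP, SNP, A1, A2, BETA, P).

    A1 is the effect allele.  Returns a DataFrame with normalized
    chromosome labels; validates p in (0, 1] and finite beta.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"summary stats missing required columns: {missing}")
    df = df.copy()
    df["CHR"] = df["CHR"].map(normalize_chrom)
    if not np.isfinite(df["BETA"].to_numpy(float)).all():
        raise FormatError("non-finite BETA in summary stats")
    p = df["P"].to_numpy(float)
    if ((p <= 0) | (p > 1)).any():
        raise FormatError("P values must lie in (0, 1]")
    return df


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene intervals from refGene-style TSV or 4-column BED.

    refGene TSV has a header with columns (gene, chrom, txStart, txEnd),
    1-based inclusive; BED (detected by ``.bed`` extension) is 0-based
    half-open with columns (chrom, start, end, gene).  Output columns:
    gene, chrom, start, end — 0-based half-open.
    """
    path = str(path)
    if path.endswith(".bed"):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "gene"]
        )
        out = df[["gene", "chrom", "start", "end"]].copy()
    else:
        df = pd.read_csv(path, sep="\t")
        need = {"gene", "chrom", "txStart", "txEnd"}
        if not need.issubset(df.columns):
            raise FormatError(f"gene annotation needs columns {sorted(need)}")
        out = pd.DataFrame(
            {
                "gene": df["gene"],
                "chrom": df["chrom"],
                "start": df["txStart"].astype(int) - 1,
                "end": df["txEnd"].astype(int),
            }
        )
    out["chrom"] = out["chrom"].map(normalize_chrom)
    if (out["start"] >= out["end"]).any():
        raise FormatError("gene annotation contains empty/inverted intervals")
    if out.duplicated(subset=["gene", "chrom"]).any():
        raise FormatError("duplicate (gene, chrom) pairs in annotation")
    return out.reset_index(drop=True)


def read_phenotypes(path) -> pd.DataFrame:
    """Read the per-sample phenotype table.

    Required columns: sample, age, sex, apoe, fdg_suvr, av45_suvr, the
    five cognitive scores, and ``visits`` as a comma-separated diagnosis
    sequence (e.g. ``CN,CN,EMCI``).  Returns a DataFrame indexed by
    sample with ``visits`` parsed to tuples.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "apoe": str})
    need = {"sample", "age", "sex", "apoe", "fdg_suvr", "av45_suvr", "visits"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
    df = df.set_index("sample")
    df["visits"] = df["visits"].map(_parse_visits)
    return df


def _parse_visits(text) -> tuple[str, ...]:
    if pd.isna(text) or str(text).strip() == "":
        return ()
    toks = tuple(t.strip() for t in str(text).split(","))
    bad = [t for t in toks if t not in DIAGNOSES]
    if bad:
        raise FormatError(f"unknown diagnosis tokens {bad}; allowed {DIAGNOSES}")
    return toks


def align_alleles(geno: GenotypeMatrix, sumstats: pd.DataFrame) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Orient dosages onto the summary-statistics effect allele (A1).

    Variants are matched by ID when the ID is present in both sources,
    else by (chrom, pos).  Where A1 equals the genotype REF allele the
    dosage is replaced by ``2 - dosage`` and the effect allele updated;
    where neither A1 nor A2 matches the variant's allele pair the
    variant is dropped.  Unmatched variants are retained but flagged.

    Returns the aligned matrix and a per-variant report with columns
    (vid, status) where status is one of kept/flipped/unmatched; dropped
    variants appear with status ``dropped``.
    """
    by_id = {str(s): i for i, s in enumerate(sumstats["SNP"])}
    by_pos = {
        (normalize_chrom(c), int(b)): i
        for i, (c, b) in enumerate(zip(sumstats["CHR"], sumstats["BP"]))
    }
    a1 = sumstats["A1"].astype(str).to_numpy()
    a2 = sumstats["A2"].astype(str).to_numpy()

    keep_idx: list[int] = []
    new_variants: list[VariantRecord] = []
    flip_cols: list[int] = []
    report_rows: list[tuple[str, str]] = []
    for i, v in enumerate(geno.variants):
        row = by_id.get(v.vid)
        if row is None:
            row = by_pos.get((v.chrom, v.pos))
        if row is None:
            keep_idx.append(i)
            new_variants.append(v)
            report_rows.append((v.vid, "unmatched"))
            continue
        ea, oa = a1[row], a2[row]
        if {ea, oa} != {v.ref_allele, v.alt_allele}:
            report_rows.append((v.vid, "dropped"))
            continue
        keep_idx.append(i)
        if ea == v.effect_allele:  # already oriented (idempotent)
            new_variants.append(v)
            report_rows.append((v.vid, "kept"))
        else:
            new_variants.append(replace(v, effect_allele=ea))
            flip_cols.append(len(keep_idx) - 1)
            report_rows.append((v.vid, "flipped"))
    n_dropped = sum(1 for _, s in report_rows if s == "dropped")
    if n_dropped:
        warnings.warn(f"align_alleles dropped {n_dropped} variants with mismatched allele pairs")
    out = geno.subset_variants(np.asarray(keep_idx, dtype=int))
    out.variants = new_variants
    if flip_cols:
        cols = np.asarray(flip_cols, dtype=int)
        out.dosage[:, cols] = 2.0 - out.dosage[:, cols]
    report = pd.DataFrame(report_rows, columns=["vid", "status"])
    return out, report


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a score table as TSV (sample, score, model_name[, task]).

    Scores are printed with ``repr``-round-trip precision so that
    :func:`read_scores` recovers bit-identical values.
    """
    need = {"sample", "score", "model_name"}
    if not need.issubset(scores.columns):
        raise ValueError(f"score table needs columns {sorted(need)}")
    if scores.duplicated(subset=[c for c in ("sample", "model_name", "task") if c in scores.columns]).any():
        raise ValueError("duplicate (sample, model) rows in score table")
    out = scores.copy()
    # shortest representation that uniquely round-trips the float
    out["score"] = out["score"].map(lambda x: np.format_float_scientific(x, unique=True))
    out.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str}, float_precision="round_trip")
    df["score"] = df["score"].astype(float)
    return df
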