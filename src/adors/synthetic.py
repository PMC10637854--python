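"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a WGS + PET cohort: block-structured common
variant dosages, a small set of causal genes whose direction-corrected
burdens drive both the imaging endophenotypes (FDG-PET down, AV45-PET
up) and the case/control liability, an APOE allele score entering the
liability, cognitive assessments loaded on the liability with the
clinically observed sign pattern, and longitudinal visit sequences
consistent with case status.  GWAS summary statistics are estimated on
an independent replicate cohort drawn from the same truth, mimicking
the external-GWAS structure a PRS assumes (weights never come from the
analysis cohort itself).

A liability-threshold model sets case status: the top
``case_fraction`` quantile of liability converts, so label prevalence
tracks the configured fraction by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import COGNITIVE_SCORES, GenotypeMatrix, VariantRecord
from .models import APOEWeights, apoe_score

__all__ = ["SimConfig", "SimulatedCohort", "simulate_cohort", "export_fixture"]

#: loading sign of each cognitive test on liability (worse cognition in cases)
COGNITIVE_SIGNS = {"ADAS13": 1, "CDRSB": 1, "FAQ": 1, "MMSE": -1, "RAVLT": -1}
_COGNITIVE_BASE = {
    "ADAS13": (17.0, 6.0),
    "CDRSB": (1.5, 1.2),
    "FAQ": (4.0, 4.0),
    "MMSE": (27.0, 1.8),
    "RAVLT": (4.0, 2.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator parameters.

    Defaults are sized to a single-task ADNI-scale cohort: ~1000
    samples, 200 genes of ~10 common variants each, 10 causal genes
    whose burdens correlate with each PET biomarker at r ~ 0.3 in the
    population, and a liability with roughly balanced genetic, APOE
    and noise shares.  ``mci_fraction`` switches samples onto an MCI
    visit track (converters/non-converters) instead of the CN/AD
    track; the default cohort is a pure CN-vs-AD cohort.
    """

    n_samples: int = 1000
    n_genes: int = 200
    variants_per_gene: tuple[int, int] = (5, 15)
    n_intergenic_variants: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_genes: int = 10
    imaging_effect: float = 0.3  # per-gene burden weight on each PET signal
    imaging_noise_sd: float = 2.0
    liability_effect: float = 0.25  # per-gene burden weight on liability
    liability_noise_sd: float = 1.5
    apoe_freqs: tuple[float, float, float] = (0.08, 0.77, 0.15)  # e2, e3, e4
    apoe_liability_weight: float = 1.0
    apoe_weights: APOEWeights = field(default_factory=APOEWeights)
    age_mean: float = 74.0
    age_sd: float = 7.0
    age_liability_weight: float = 0.02  # per year from the mean
    sex_liability_weight: float = 0.3  # male indicator
    cognitive_loading: float = 0.6
    cognitive_noise_sd: float = 0.8
    cognitive_missing_rate: float = 0.02
    dosage_missing_rate: float = 0.01
    case_fraction: float = 0.5
    mci_fraction: float = 0.0
    visit_length: tuple[int, int] = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.apoe_freqs) - 1.0) > 1e-9:
            raise ValueError("APOE allele frequencies must sum to 1")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("more causal genes than genes")
        if self.imaging_noise_sd <= 0 or self.liability_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth that produced it."""

    genotypes: GenotypeMatrix
    sumstats: pd.DataFrame
    annotation: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict


def _layout(cfg: SimConfig, rng: np.random.Generator):
    """Gene intervals, variant placement, per-variant MAFs and signs."""
    n_var_per_gene = rng.integers(
        cfg.variants_per_gene[0], cfg.variants_per_gene[1] + 1, size=cfg.n_genes
    )
    genes, variants, gene_of_variant = [], [], []
    per_chrom_cursor: dict[str, int] = {}
    for g in range(cfg.n_genes):
        chrom = str((g % 22) + 1)
        cursor = per_chrom_cursor.get(chrom, 1_000_000)
        n_v = int(n_var_per_gene[g])
        start0 = cursor  # 0-based half-open
        end0 = cursor + n_v * 1000 + 500
        name = f"GENE{g:04d}"
        genes.append({"gene": name, "chrom": chrom, "start": start0, "end": end0})
        for k in range(n_v):
            pos = start0 + 250 + k * 1000 + 1  # 1-based, inside [start0, end0)
            variants.append((chrom, pos))
            gene_of_variant.append(name)
        per_chrom_cursor[chrom] = end0 + 2_000_000
    for k in range(cfg.n_intergenic_variants):
        chrom = str((k % 22) + 1)
        cursor = per_chrom_cursor.get(chrom, 1_000_000)
        variants.append((chrom, cursor + 500_000 + 1))
        gene_of_variant.append(None)
        per_chrom_cursor[chrom] = cursor + 1_000_000
    mafs = rng.uniform(*cfg.maf_range, size=len(variants))
    causal_genes = sorted(
        str(g)
        for g in rng.choice(
            [g["gene"] for g in genes], size=cfg.n_causal_genes, replace=False
        )
    )
    signs = np.where(rng.random(len(variants)) < 0.5, -1, 1)
    return genes, variants, gene_of_variant, mafs, causal_genes, signs


_ALLELES = ["A", "C", "G", "T"]


def _draw_cohort(cfg, rng, variants, mafs, gene_of_variant, causal_genes, signs):
    """Dosages plus the centered causal-gene burden signal per sample."""
    n = cfg.n_samples
    dosage = rng.binomial(2, mafs[None, :], size=(n, len(mafs))).astype(float)
    causal = set(causal_genes)
    # direction-corrected true burden per causal gene, centered
    signal = np.zeros(n)
    per_gene_burden = {}
    for g in causal:
        idx = [k for k, gg in enumerate(gene_of_variant) if gg == g]
        s = np.where(signs[idx][None, :] < 0, 2.0 - dosage[:, idx], dosage[:, idx])
        v = s.sum(axis=1)
        per_gene_burden[g] = v
        signal = signal + (v - v.mean())
    return dosage, signal, per_gene_burden


def simulate_cohort(cfg: SimConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Generate a cohort; same config and seed give identical output."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes, variants, gene_of_variant, mafs, causal_genes, signs = _layout(cfg, rng)
    n = cfg.n_samples

    dosage, signal, _ = _draw_cohort(
        cfg, rng, variants, mafs, gene_of_variant, causal_genes, signs
    )

    # phenotypes driven by the causal burden signal
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    sex = rng.integers(0, 2, size=n)  # 1 = male
    apoe_geno = _draw_apoe(rng, cfg.apoe_freqs, n)
    apoe_vals = np.array([apoe_score(g, cfg.apoe_weights) for g in apoe_geno])

    g_signal = cfg.liability_effect * signal
    liability = (
        g_signal
        + cfg.apoe_liability_weight * (apoe_vals - apoe_vals.mean())
        + cfg.age_liability_weight * (age - cfg.age_mean)
        + cfg.sex_liability_weight * (sex - 0.5)
        + rng.normal(0.0, cfg.liability_noise_sd, size=n)
    )
    threshold = np.quantile(liability, 1.0 - cfg.case_fraction)
    case = liability >= threshold

    img = cfg.imaging_effect * signal
    av45 = 1.20 + 0.10 * (img + rng.normal(0, cfg.imaging_noise_sd, n))
    fdg = 1.30 - 0.10 * (img + rng.normal(0, cfg.imaging_noise_sd, n))

    z_l = (liability - liability.mean()) / liability.std()
    cognitive = {}
    for test in COGNITIVE_SCORES:
        base, scale = _COGNITIVE_BASE[test]
        sgn = COGNITIVE_SIGNS[test]
        raw = sgn * cfg.cognitive_loading * z_l + rng.normal(0, cfg.cognitive_noise_sd, n)
        vals = base + scale * raw
        miss = rng.random(n) < cfg.cognitive_missing_rate
        vals = np.where(miss, np.nan, vals)
        cognitive[test] = vals

    visits = [
        _visit_sequence(rng, bool(c), rng.random() < cfg.mci_fraction, cfg.visit_length)
        for c in case
    ]

    if cfg.dosage_missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.dosage_missing_rate
        dosage = np.where(miss, np.nan, dosage)

    sample_ids = [f"S{i:05d}" for i in range(n)]
    var_records = []
    for k, (chrom, pos) in enumerate(variants):
        ref, alt = rng.choice(_ALLELES, size=2, replace=False)
        var_records.append(
            VariantRecord(chrom, pos, f"rs{k:06d}", ref, alt, effect_allele=alt)
        )
    geno = GenotypeMatrix(samples=sample_ids, variants=var_records, dosage=dosage)

    phenotypes = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(sex == 1, "male", "female"),
            "apoe": apoe_geno,
            "fdg_suvr": fdg,
            "av45_suvr": av45,
            **cognitive,
            "visits": [tuple(v) for v in visits],
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    sumstats = _replicate_sumstats(
        cfg, rng, var_records, mafs, gene_of_variant, causal_genes, signs
    )
    annotation = pd.DataFrame(genes)

    truth = {
        "causal_genes": list(causal_genes),
        "liability_effect": cfg.liability_effect,
        "imaging_effect": cfg.imaging_effect,
        "variant_signs": {v.vid: int(s) for v, s in zip(var_records, signs)},
        "gene_of_variant": {
            v.vid: g for v, g in zip(var_records, gene_of_variant) if g is not None
        },
        "case_threshold": float(threshold),
        "seed": int(cfg.seed if seed is None else seed),
        "case": {s: bool(c) for s, c in zip(sample_ids, case)},
    }
    return SimulatedCohort(geno, sumstats, annotation, phenotypes, truth)


def _draw_apoe(rng, freqs, n):
    alleles = rng.choice([2, 3, 4], size=(n, 2), p=list(freqs))
    alleles.sort(axis=1)
    return [f"e{a}e{b}" for a, b in alleles]


def _visit_sequence(rng, case: bool, mci_track: bool, length_range) -> list[str]:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    if not mci_track:
        return ["AD"] * length if case else ["CN"] * length
    mci_states = ["EMCI", "LMCI"]
    if case:  # converter: MCI prefix then AD maintained to the end
        conv_at = int(rng.integers(1, length))
        prefix = [mci_states[int(rng.integers(0, 2))] for _ in range(conv_at)]
        return prefix + ["AD"] * (length - conv_at)
    return [mci_states[int(rng.integers(0, 2))] for _ in range(length)]


def _replicate_sumstats(cfg, rng, var_records, mafs, gene_of_variant, causal_genes, signs):
    """Per-variant association estimated on an independent replicate cohort.

    Betas are linear (score-test) regression coefficients of case
    status on dosage, with p-values from the correlation t-test; the
    signs and p-value ranks are what downstream consumes.
    """
    n = cfg.n_samples
    dosage, signal, _ = _draw_cohort(
        cfg, rng, [(v.chrom, v.pos) for v in var_records], mafs, gene_of_variant,
        causal_genes, signs,
    )
    apoe_vals = np.array(
        [apoe_score(g, cfg.apoe_weights) for g in _draw_apoe(rng, cfg.apoe_freqs, n)]
    )
    liability = (
        cfg.liability_effect * signal
        + cfg.apoe_liability_weight * (apoe_vals - apoe_vals.mean())
        + rng.normal(0.0, cfg.liability_noise_sd, size=n)
    )
    y = (liability >= np.quantile(liability, 1.0 - cfg.case_fraction)).astype(float)

    x = dosage
    xm = x - x.mean(axis=0)
    ym = y - y.mean()
    var_x = (xm**2).mean(axis=0)
    var_x[var_x == 0] = np.nan
    beta = (xm * ym[:, None]).mean(axis=0) / var_x
    r = (xm * ym[:, None]).mean(axis=0) / np.sqrt(var_x * (ym**2).mean())
    r = np.clip(np.nan_to_num(r, nan=0.0), -0.999999, 0.999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    beta = np.nan_to_num(beta, nan=0.0)

    return pd.DataFrame(
        {
            "CHR": [v.chrom for v in var_records],
            "BP": [v.pos for v in var_records],
            "SNP": [v.vid for v in var_records],
            "A1": [v.alt_allele for v in var_records],
            "A2": [v.ref_allele for v in var_records],
            "BETA": beta,
            "P": p,
        }
    )


def export_fixture(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write the cohort in the pipeline's external formats.

    Produces genotypes.vcf, sumstats.tsv, annotation.tsv (refGene
    style, 1-based inclusive), phenotypes.tsv and truth.json; returns
    the paths.  Round-tripping through the io readers reproduces the
    in-memory objects.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: str(outdir / f) for k, f in [
        ("genotypes", "genotypes.vcf"),
        ("sumstats", "sumstats.tsv"),
        ("annotation", "annotation.tsv"),
        ("phenotypes", "phenotypes.tsv"),
        ("truth", "truth.json"),
    ]}

    _write_vcf(cohort.genotypes, paths["genotypes"])
    cohort.sumstats.to_csv(paths["sumstats"], sep="\t", index=False)
    ann = cohort.annotation.copy()
    ann["txStart"] = ann["start"] + 1  # back to 1-based inclusive
    ann["txEnd"] = ann["end"]
    ann[["gene", "chrom", "txStart", "txEnd"]].to_csv(
        paths["annotation"], sep="\t", index=False
    )
    ph = cohort.phenotypes.copy()
    ph["visits"] = ph["visits"].map(",".join)
    ph.to_csv(paths["phenotypes"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return paths


def _write_vcf(geno: GenotypeMatrix, path: str) -> None:
    # sort records by (chrom, pos) as VCF consumers expect
    order = sorted(
        range(geno.n_variants),
        key=lambda i: (int(geno.variants[i].chrom), geno.variants[i].pos),
    )
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({int(v.chrom) for v in geno.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for i in order:
            v = geno.variants[i]
            calls = [
                gt_of.get(d, "./.") if not np.isnan(d) else "./."
                for d in geno.dosage[:, i]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )
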