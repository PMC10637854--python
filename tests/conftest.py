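import numpy as np
import pandas as pd
import pytest

from adors.io_formats import GenotypeMatrix, VariantRecord
from adors.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort shared across read-only tests."""
    cfg = SimConfig(
        n_samples=300, n_genes=40, n_causal_genes=5, n_intergenic_variants=6, seed=7
    )
    return simulate_cohort(cfg)


def random_genotypes(rng, n_samples, n_variants, chrom="1", spacing=10_000, missing=0.0):
    """Ad-hoc genotype matrix with evenly spaced variants on one chromosome."""
    dosage = rng.integers(0, 3, size=(n_samples, n_variants)).astype(float)
    if missing > 0:
        dosage[rng.random(dosage.shape) < missing] = np.nan
    variants = [
        VariantRecord(chrom, 1000 + k * spacing, f"v{k}", "A", "G", "G")
        for k in range(n_variants)
    ]
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)], variants=variants, dosage=dosage
    )


VCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=19>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB\tsampleC\tsampleD
1\t100\trs1\tA\tG\t.\t.\t.\tGT:GQ:DP\t0/0:99:30\t0/1:19:30\t1/1:99:30\t./.:99:30
1\t200\trs2\tC\tT\t.\t.\t.\tGT:GQ:DP\t0/1:99:9\t0/1:99:30\t0/0:20:10\t0/0:99:30
1\t300\trs3\tG\tA,C\t.\t.\t.\tGT:GQ:DP\t0/1:99:30\t0/2:99:30\t0/0:99:30\t1/1:99:30
1\t400\trs4\tT\tC\t.\t.\t.\tGT:GQ:DP\t1/1:99:30\t0/0:99:30\t0/1:99:30\t0/1:99:30
19\t45000000\trs5\tG\tC\t.\t.\t.\tGT:GQ:DP\t0/1:99:30\t0/0:99:30\t0/0:99:30\t1/1:99:30
"""


@pytest.fixture()
def vcf_path(tmp_path):
    p = tmp_path / "fixture.vcf"
    p.write_text(VCF_FIXTURE)
    return str(p)
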