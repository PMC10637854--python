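"""Clumping + thresholding PRS comparator."""

import numpy as np
import pandas as pd
import pytest

from adors.io_formats import GenotypeMatrix, VariantRecord
from adors.prs import ClumpConfig, build_prs_model, clump, prs_score

from conftest import random_genotypes


def _sumstats(variants, betas, pvals):
    return pd.DataFrame(
        {
            "CHR": [v.chrom for v in variants],
            "BP": [v.pos for v in variants],
            "SNP": [v.vid for v in variants],
            "A1": [v.alt_allele for v in variants],
            "A2": [v.ref_allele for v in variants],
            "BETA": betas,
            "P": pvals,
        }
    )


def clump_oracle(ss, geno, cfg):
    """Independent greedy scan coded over explicit candidate lists."""
    col = {v.vid: i for i, v in enumerate(geno.variants)}
    rows = [
        r
        for r in ss.to_dict("records")
        if not cfg.apoe_region.contains_pos(r["CHR"], int(r["BP"]))
        and r["SNP"] in col
    ]
    rows.sort(key=lambda r: (r["P"], str(r["CHR"]), int(r["BP"])))
    retained, removed = [], set()
    for r in rows:
        if r["SNP"] in removed:
            continue
        retained.append(r["SNP"])
        for other in rows:
            if other["SNP"] in removed or other["SNP"] == r["SNP"]:
                continue
            if other["SNP"] in retained:
                continue
            if str(other["CHR"]) != str(r["CHR"]):
                continue
            if abs(int(other["BP"]) - int(r["BP"])) > cfg.window_kb * 1000:
                continue
            a = geno.dosage[:, col[r["SNP"]]]
            b = geno.dosage[:, col[other["SNP"]]]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
                continue
            if np.corrcoef(a[ok], b[ok])[0, 1] ** 2 > cfg.r2_max:
                removed.add(other["SNP"])
    return retained


class TestClump:
    def test_single_variant_retained(self):
        geno = random_genotypes(np.random.default_rng(0), 50, 1)
        ss = _sumstats(geno.variants, [0.1], [1e-6])
        kept, _ = clump(ss, geno)
        assert list(kept["SNP"]) == ["v0"]

    def test_duplicate_dosage_neighbours_keep_best_p(self):
        rng = np.random.default_rng(61)
        d = rng.integers(0, 3, size=(100, 1)).astype(float)
        geno = GenotypeMatrix(
            [f"s{i}" for i in range(100)],
            [
                VariantRecord("1", 100_000, "a", "A", "G", "G"),
                VariantRecord("1", 110_000, "b", "A", "G", "G"),
            ],
            np.hstack([d, d]),  # r^2 = 1
        )
        ss = _sumstats(geno.variants, [0.2, 0.2], [1e-8, 1e-6])
        kept, provenance = clump(ss, geno)
        assert list(kept["SNP"]) == ["a"]
        assert provenance == {"b": "a"}

    def test_correlated_pair_outside_window_both_retained(self):
        rng = np.random.default_rng(62)
        d = rng.integers(0, 3, size=(100, 1)).astype(float)
        geno = GenotypeMatrix(
            [f"s{i}" for i in range(100)],
            [
                VariantRecord("1", 1_000_000, "a", "A", "G", "G"),
                VariantRecord("1", 3_000_000, "b", "A", "G", "G"),  # 2000 kb away
            ],
            np.hstack([d, d]),
        )
        ss = _sumstats(geno.variants, [0.2, 0.2], [1e-8, 1e-6])
        kept, _ = clump(ss, geno)
        assert sorted(kept["SNP"]) == ["a", "b"]

    def test_apoe_region_removed_before_clumping(self):
        geno = GenotypeMatrix(
            ["s1", "s2", "s3"],
            [
                VariantRecord("19", 45_000_000, "inapoe", "A", "G", "G"),
                VariantRecord("19", 47_000_000, "out", "A", "G", "G"),
            ],
            [[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]],
        )
        ss = _sumstats(geno.variants, [0.3, 0.1], [1e-10, 1e-6])
        kept, _ = clump(ss, geno)
        assert list(kept["SNP"]) == ["out"]

    def test_random_instances_match_independent_greedy_oracle(self):
        rng = np.random.default_rng(63)
        cfg = ClumpConfig(window_kb=50, r2_max=0.2)
        for _ in range(30):
            n_var = int(rng.integers(5, 60))
            geno = random_genotypes(rng, 60, n_var, spacing=int(rng.integers(5_000, 40_000)))
            ss = _sumstats(
                geno.variants,
                rng.normal(size=n_var),
                10 ** (-rng.uniform(0, 8, size=n_var)),
            )
            kept, _ = clump(ss, geno, cfg)
            assert list(kept["SNP"]) == clump_oracle(ss, geno, cfg)
            # post-hoc: no retained pair violates the window/r2 rule
            col = {v.vid: i for i, v in enumerate(geno.variants)}
            ids = list(kept["SNP"])
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    va, vb = geno.variants[col[a]], geno.variants[col[b]]
                    if va.chrom != vb.chrom or abs(va.pos - vb.pos) > cfg.window_kb * 1000:
                        continue
                    r2 = np.corrcoef(
                        geno.dosage[:, col[a]], geno.dosage[:, col[b]]
                    )[0, 1] ** 2
                    assert r2 <= cfg.r2_max + 1e-12

    def test_retained_set_invariant_to_input_order(self):
        rng = np.random.default_rng(64)
        geno = random_genotypes(rng, 60, 30, spacing=8_000)
        ss = _sumstats(
            geno.variants, rng.normal(size=30), 10 ** (-rng.uniform(0, 8, size=30))
        )
        cfg = ClumpConfig(window_kb=50, r2_max=0.2)
        kept1, _ = clump(ss, geno, cfg)
        kept2, _ = clump(ss.sample(frac=1.0, random_state=1), geno, cfg)
        assert list(kept1["SNP"]) == list(kept2["SNP"])

    def test_lower_threshold_never_adds_variants(self):
        rng = np.random.default_rng(65)
        geno = random_genotypes(rng, 60, 40, spacing=8_000)
        ss = _sumstats(
            geno.variants, rng.normal(size=40), 10 ** (-rng.uniform(0, 8, size=40))
        )
        cfg = ClumpConfig(window_kb=50, r2_max=0.2)
        previous = None
        for thr in (0.5, 0.1, 1e-3, 1e-5, 5e-8):
            model = build_prs_model(ss, geno, cfg, threshold=thr)
            snps = set(model.snp_ids)
            if previous is not None:
                assert snps <= previous
            previous = snps


class TestPrsScore:
    def test_single_variant_arithmetic(self):
        geno = GenotypeMatrix(
            ["s1"], [VariantRecord("1", 100, "v0", "A", "G", "G")], [[2.0]]
        )
        ss = _sumstats(geno.variants, [0.3], [1e-8])
        model = build_prs_model(ss, geno)
        st = prs_score(model, geno)
        assert st["score"].iloc[0] == pytest.approx(0.6)

    def test_all_zero_dosages_score_zero(self):
        geno = GenotypeMatrix(
            ["s1", "s2"],
            [VariantRecord("1", 100, "v0", "A", "G", "G")],
            [[0.0], [0.0]],
        )
        ss = _sumstats(geno.variants, [0.3], [1e-8])
        st = prs_score(build_prs_model(ss, geno), geno)
        assert (st["score"] == 0.0).all()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(66)
        geno = random_genotypes(rng, 30, 100, spacing=2_000_000)
        betas = rng.normal(size=100)
        ss = _sumstats(geno.variants, betas, np.full(100, 1e-8))
        model = build_prs_model(ss, geno, ClumpConfig(window_kb=10, r2_max=0.99))
        st = prs_score(model, geno)
        beta_of = dict(zip(ss["SNP"], ss["BETA"]))
        col = {v.vid: i for i, v in enumerate(geno.variants)}
        for i in range(30):
            expected = sum(
                beta_of[s] * geno.dosage[i, col[s]] for s in model.snp_ids
            )
            assert st["score"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_empty_retained_set_rejected(self):
        geno = random_genotypes(np.random.default_rng(67), 10, 2)
        ss = _sumstats(geno.variants, [0.1, 0.2], [0.9, 0.8])
        model = build_prs_model(ss, geno, threshold=1e-5)
        with pytest.raises(ValueError, match="no variants"):
            prs_score(model, geno)
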