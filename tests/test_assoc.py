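"""Association scan, meta-analysis, inflation factor, index SNPs, sign test."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from conftest import make_geno, small_genotypes

from polyhet.assoc import (
    align_alleles,
    genome_wide_regions,
    genomic_lambda,
    logistic_assoc_scan,
    meta_analyze_fixed,
    select_index_snps,
    select_mds_covariates,
    sign_test,
)


def _sumstats(snps, betas, ses, ps=None, a1="A", a2="G", chrom=1, bp=None):
    n = len(snps)
    if ps is None:
        ps = 2 * stats.norm.sf(np.abs(np.asarray(betas) / np.asarray(ses)))
    return pd.DataFrame(
        {
            "SNP": snps,
            "CHR": chrom,
            "BP": np.arange(1, n + 1) * 1000 if bp is None else bp,
            "A1": a1,
            "A2": a2,
            "FRQ": 0.3,
            "BETA": betas,
            "SE": ses,
            "P": ps,
        }
    )


class TestMdsCovariateSelection:
    def test_phenotype_like_component_selected(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 400).astype(float)
        comps = rng.normal(size=(400, 10))
        comps[:, 3] = y + rng.normal(0, 0.5, 400)
        sel = select_mds_covariates(comps, y)
        assert 3 in sel

    def test_alpha_zero_selects_none(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200).astype(float)
        assert select_mds_covariates(rng.normal(size=(200, 10)), y, alpha=0.0) == []

    def test_constant_phenotype_errors(self):
        with pytest.raises(ValueError):
            select_mds_covariates(np.random.normal(size=(50, 10)), np.ones(50))


class TestLogisticScan:
    def test_matches_statsmodels_per_snp(self):
        rng = np.random.default_rng(2)
        g = small_genotypes(seed=2, n=300, m=8)
        y = rng.integers(0, 2, 300).astype(float)
        cov = rng.normal(size=(300, 2))
        scan = logistic_assoc_scan(g, y, covariates=cov)
        for j in range(8):
            X = sm.add_constant(np.column_stack([cov, g.dosages[:, j]]))
            ref = sm.Logit(y, X).fit(disp=0)
            assert scan["BETA"][j] == pytest.approx(ref.params[-1], abs=1e-6)
            assert scan["SE"][j] == pytest.approx(ref.bse[-1], abs=1e-6)

    def test_large_effect_snp_is_top_hit(self):
        rng = np.random.default_rng(3)
        n = 2000
        g = small_genotypes(seed=3, n=n, m=50)
        x = g.dosages[:, 7]
        eta = -0.5 + np.log(2.0) * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        scan = logistic_assoc_scan(g, y)
        assert scan["P"].idxmin() == 7

    def test_monomorphic_flagged_na(self):
        d = np.column_stack([np.full(100, 2.0), np.random.default_rng(0).binomial(2, 0.3, 100)])
        g = make_geno(d)
        y = np.random.default_rng(1).integers(0, 2, 100).astype(float)
        scan = logistic_assoc_scan(g, y)
        assert np.isnan(scan["BETA"][0]) and scan["REASON"][0] == "monomorphic"

    def test_rejects_nonbinary_phenotype(self):
        g = small_genotypes(seed=4, n=50, m=3)
        with pytest.raises(ValueError):
            logistic_assoc_scan(g, np.linspace(0, 1, 50))


class TestMeta:
    def test_identical_studies_closed_form(self):
        s = _sumstats(["a", "b"], [0.1, -0.2], [0.1, 0.1])
        meta = meta_analyze_fixed([s, s.copy()])
        row = meta.set_index("SNP").loc["a"]
        assert row["BETA"] == pytest.approx(0.1)
        assert row["SE"] == pytest.approx(0.1 / np.sqrt(2))
        assert row["Q"] == pytest.approx(0.0)
        assert row["HET_P"] == pytest.approx(1.0)
        assert row["DIRECTION"] == "++"

    def test_opposite_effects_cancel(self):
        s1 = _sumstats(["a"], [0.1], [0.05])
        s2 = _sumstats(["a"], [-0.1], [0.05])
        meta = meta_analyze_fixed([s1, s2])
        assert meta["BETA"][0] == pytest.approx(0.0)

    def test_three_studies_match_hand_formula(self):
        betas = [0.12, 0.08, -0.02]
        ses = [0.05, 0.08, 0.1]
        studies = [_sumstats(["x"], [b], [s]) for b, s in zip(betas, ses)]
        meta = meta_analyze_fixed(studies)
        w = 1 / np.array(ses) ** 2
        pooled = np.sum(w * betas) / w.sum()
        assert meta["BETA"][0] == pytest.approx(pooled)
        assert meta["SE"][0] == pytest.approx(1 / np.sqrt(w.sum()))
        assert meta["Q"][0] == pytest.approx(np.sum(w * (betas - pooled) ** 2))

    def test_allele_flip_invariance(self):
        s1 = _sumstats(["a", "b"], [0.1, 0.3], [0.1, 0.1])
        s2 = _sumstats(["a", "b"], [0.2, 0.1], [0.1, 0.1])
        flipped = s2.copy()
        flipped.loc[0, ["A1", "A2"]] = ["G", "A"]
        flipped.loc[0, "BETA"] = -flipped.loc[0, "BETA"]
        flipped.loc[0, "FRQ"] = 1 - flipped.loc[0, "FRQ"]
        m1 = meta_analyze_fixed([s1, s2])
        m2 = meta_analyze_fixed([s1, flipped])
        assert np.allclose(m1["BETA"], m2["BETA"])
        assert np.allclose(m1["Q"], m2["Q"])

    def test_ambiguous_snps_dropped(self):
        s1 = _sumstats(["a", "b"], [0.1, 0.3], [0.1, 0.1], a1="A", a2="T")
        s2 = _sumstats(["a", "b"], [0.2, 0.1], [0.1, 0.1], a1="A", a2="T")
        with pytest.raises(ValueError, match="no overlapping"):
            meta_analyze_fixed([s1, s2])


class TestGenomicLambda:
    def test_uniform_null_near_one(self):
        rng = np.random.default_rng(5)
        lam = genomic_lambda(rng.uniform(size=100_000))
        assert 0.99 <= lam <= 1.01

    def test_median_chi_square_exactly_one(self):
        p = np.full(99, stats.chi2.sf(stats.chi2.ppf(0.5, 1), 1))
        assert genomic_lambda(p) == pytest.approx(1.0)

    def test_inflated_statistics_recovered(self):
        rng = np.random.default_rng(6)
        chi = stats.chi2.rvs(1, size=200_000, random_state=rng) * 1.11
        lam = genomic_lambda(stats.chi2.sf(chi, 1))
        assert lam == pytest.approx(1.11, abs=0.02)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            genomic_lambda(np.array([np.nan]))


class TestIndexSnps:
    def test_duplicated_signal_collapses_to_one(self):
        rng = np.random.default_rng(7)
        base = rng.binomial(2, 0.4, 500).astype(float)
        g = make_geno(np.column_stack([base, base, rng.binomial(2, 0.4, 500)]))
        s = _sumstats(["s0", "s1", "s2"], [0.5, 0.5, 0.0], [0.05, 0.05, 0.05], bp=[1000, 2000, 3000])
        idx = select_index_snps(s, 1e-4, genotypes_reference=g)
        assert len([i for i in idx if i in ("s0", "s1")]) == 1

    def test_linkage_free_keeps_all_significant(self):
        s = _sumstats(["a", "b", "c"], [0.5, 0.4, 0.01], [0.05, 0.05, 0.05])
        idx = select_index_snps(s, 1e-4)
        assert set(idx) == {"a", "b"}

    def test_block_fixture_counts(self):
        rng = np.random.default_rng(8)
        blocks = []
        for _ in range(3):
            base = rng.binomial(2, 0.5, 800).astype(float)
            noisy = np.clip(np.round(base + rng.normal(0, 0.2, 800)), 0, 2)
            blocks += [base, noisy]
        g = make_geno(np.column_stack(blocks))
        names = [f"s{j}" for j in range(6)]
        s = _sumstats(names, [0.5] * 6, [0.05] * 6, ps=[1e-9, 2e-9, 1e-8, 3e-9, 5e-9, 1e-7])
        idx = select_index_snps(s, 1e-4, r2_max=0.1, genotypes_reference=g)
        assert len(idx) == 3  # one per LD block

    def test_none_significant_empty(self):
        s = _sumstats(["a"], [0.01], [0.05])
        assert select_index_snps(s, 1e-8) == []


class TestSignTest:
    def test_eight_of_ten_exact(self):
        disc = _sumstats([f"s{i}" for i in range(10)], [0.2] * 10, [0.01] * 10)
        tgt_betas = [0.1] * 8 + [-0.1] * 2
        tgt = _sumstats([f"s{i}" for i in range(10)], tgt_betas, [0.05] * 10)
        res = sign_test(disc, tgt, thresholds=(0.5,))[0.5]
        assert res.n_concordant == 8
        assert res.binomial_p_two_sided == pytest.approx(112 / 1024)

    def test_perfect_concordance(self):
        disc = _sumstats([f"s{i}" for i in range(20)], [0.2] * 20, [0.01] * 20)
        tgt = _sumstats([f"s{i}" for i in range(20)], [0.3] * 20, [0.05] * 20)
        res = sign_test(disc, tgt, thresholds=(0.5,))[0.5]
        assert res.binomial_p_two_sided == pytest.approx(2 * 0.5**20, rel=1e-10)

    def test_half_concordance_folds_to_one(self):
        disc = _sumstats([f"s{i}" for i in range(100)], [0.2] * 100, [0.01] * 100)
        tgt = _sumstats([f"s{i}" for i in range(100)], [0.1] * 50 + [-0.1] * 50, [0.05] * 100)
        res = sign_test(disc, tgt, thresholds=(0.5,))[0.5]
        assert res.binomial_p_two_sided == pytest.approx(1.0)

    def test_missing_target_snps_counted(self):
        disc = _sumstats(["a", "b", "c"], [0.2] * 3, [0.01] * 3)
        tgt = _sumstats(["a", "b"], [0.1, 0.1], [0.05] * 2)
        res = sign_test(disc, tgt, thresholds=(0.5,))[0.5]
        assert res.n_index_snps == 2 and res.n_missing_in_target == 1

    def test_global_sign_flip_invariance(self):
        rng = np.random.default_rng(9)
        betas = rng.normal(0, 0.2, 40)
        tgt_betas = betas + rng.normal(0, 0.1, 40)
        disc = _sumstats([f"s{i}" for i in range(40)], betas, [0.01] * 40)
        tgt = _sumstats([f"s{i}" for i in range(40)], tgt_betas, [0.05] * 40)
        tgt_flip = tgt.copy()
        tgt_flip["BETA"] = -tgt_flip["BETA"]
        p1 = sign_test(disc, tgt, thresholds=(0.5,))[0.5].binomial_p_two_sided
        p2 = sign_test(disc, tgt_flip, thresholds=(0.5,))[0.5].binomial_p_two_sided
        assert p1 == pytest.approx(p2)


class TestRegions:
    def test_no_significant_empty(self):
        s = _sumstats(["a"], [0.01], [0.05])
        assert len(genome_wide_regions(s)) == 0

    def test_nearby_hits_merge(self):
        s = _sumstats(["a", "b"], [0.9, 0.8], [0.05, 0.05], bp=[100_000, 200_000])
        regions = genome_wide_regions(s)
        assert len(regions) == 1 and regions["N_SNPS"][0] == 2

    def test_three_clusters_counted(self):
        bp = [1e6, 1.01e6, 5e6, 9e6, 9.1e6, 9.2e6]
        names = [f"s{i}" for i in range(6)]
        s = _sumstats(names, [1.0] * 6, [0.05] * 6, bp=bp)
        regions = genome_wide_regions(s, merge_kb=250)
        assert list(regions["N_SNPS"]) == [2, 1, 3]
        assert regions["INDEX_SNP"].notna().all()
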