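"""QC ladder: planted-offender removal, exact HWE, pruning, MDS, relatedness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_geno, small_genotypes
from _oracles import hwe_enumeration

from polyhet.qc import (
    QCThresholds,
    detect_ancestry_outliers,
    hwe_exact_test,
    ibd_pihat,
    ibd_pihat_filter,
    ibs_mds,
    ibs_similarity,
    individual_qc_filter,
    ld_prune_vif,
    post_imputation_filter,
    snp_qc_filter,
)
from polyhet.simulate import SimulationConfig, simulate_genotypes


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((100, 0, 0), 1.0),     # monomorphic: single attainable table
            ((25, 50, 25), 1.0),    # observed table is the conditional mode
        ],
    )
    def test_known_values(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected)

    def test_all_heterozygote_excess_is_extreme(self):
        assert hwe_exact_test(0, 100, 0) < 1e-20

    def test_agrees_with_direct_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(5, 200))
            aa = int(rng.integers(0, n + 1))
            ab = int(rng.integers(0, n - aa + 1))
            bb = n - aa - ab
            assert hwe_exact_test(aa, ab, bb) == pytest.approx(
                hwe_enumeration(aa, ab, bb), abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestSnpAndIndividualFilters:
    def _pheno(self, geno, n_cases):
        status = np.r_[np.ones(n_cases, int), np.zeros(geno.n_samples - n_cases, int)]
        return pd.DataFrame(
            {
                "sample_id": geno.samples,
                "status": status,
                "subtype": np.where(status == 1, "BD1", "none"),
                "site": "s1",
            }
        )

    def test_missingness_pass1_thresholds(self):
        rng = np.random.default_rng(0)
        n = 100
        d = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        for j, miss in enumerate([0.0, 0.01, 0.03, 0.06, 0.10]):
            k = int(round(miss * n))
            if k:
                d[:k, j] = np.nan
        g = make_geno(d)
        thr = QCThresholds(indiv_het_max=1.0)  # common-SNP panel: het filter off-topic here
        clean, report = snp_qc_filter(g, self._pheno(g, 50), thr)
        stage = report.stages[0]
        assert stage.name == "snp_missing_pass1"
        assert sorted(stage.removed_ids) == ["s3", "s4"]
        assert report.telescopes()

    def test_maf_boundary(self):
        rng = np.random.default_rng(1)
        n = 1000
        d = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        # plant exact MAFs: 0.009 and 0.011
        for j, count in enumerate([18, 22]):
            d[:, j] = 0.0
            d[:count, j] = 1.0
        g = make_geno(d)
        clean, report = snp_qc_filter(g, self._pheno(g, 500), QCThresholds(indiv_het_max=1.0))
        maf_stage = [s for s in report.stages if s.name == "maf"][0]
        assert maf_stage.removed_ids == ["s0"]
        assert "s1" in list(clean.snps["snp"])

    def test_differential_missingness_detected(self):
        rng = np.random.default_rng(2)
        n = 1000
        # enough SNPs that one missing call stays under the individual
        # missingness bound (1/60 < 2%)
        d = rng.binomial(2, 0.4, size=(n, 60)).astype(float)
        # SNP 0 missing in 3% of cases (first 500), never in controls;
        # overall rate 1.5% stays under both missingness passes
        d[:15, 0] = np.nan
        g = make_geno(d)
        # direct two-proportion chi-square confirms significance
        chi2, p, _, _ = stats.chi2_contingency(
            [[15, 485], [0, 500]], correction=False
        )
        assert p < 1e-3
        clean, report = snp_qc_filter(g, self._pheno(g, 500), QCThresholds(indiv_het_max=1.0))
        dm = [s for s in report.stages if s.name == "diff_missing"][0]
        assert dm.removed_ids == ["s0"]

    def test_heterozygosity_and_missingness_individual_filters(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.5, size=(50, 60)).astype(float)
        d[0, :] = 1.0            # het rate 1.0 -> removed
        d[1, :31] = np.nan       # >50% missing -> removed
        d[2, :] = rng.binomial(2, 0.5, 60)
        g = make_geno(d)
        clean, report = individual_qc_filter(g, QCThresholds(indiv_het_max=0.6, indiv_missing_max=0.2))
        removed = {i for s in report.stages for i in s.removed_ids}
        assert "i0" in removed and "i1" in removed
        assert report.telescopes()

    def test_het_filter_matches_direct_recount(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.15, size=(100, 200)).astype(float)
        g = make_geno(d)
        thr = QCThresholds(indiv_het_max=0.25, indiv_missing_max=1.0)
        clean, report = individual_qc_filter(g, thr)
        het = (d == 1).mean(axis=1)
        expect = set(g.samples[het > 0.25])
        assert set(report.stages[0].removed_ids) == expect

    def test_qc_idempotent(self, tiny_cohort):
        _, geno, pheno, _ = tiny_cohort
        thr = QCThresholds(indiv_het_max=1.0)  # common-SNP panel
        clean, _ = snp_qc_filter(geno, pheno, thr)
        again, report2 = snp_qc_filter(clean, pheno, thr)
        assert sum(s.n_removed for s in report2.stages) == 0


class TestLdPruneVif:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(200, 10)).astype(float)
        d[:, 5] = d[:, 4]
        g = make_geno(d)
        kept = ld_prune_vif(g, window=10, shift=5, vif_max=2.0)
        assert ("s4" in kept) != ("s5" in kept)  # exactly one of the pair

    def test_independent_snps_untouched(self):
        g = small_genotypes(seed=9, n=1500, m=30)
        kept = ld_prune_vif(g, window=15, shift=7, vif_max=2.0)
        assert len(kept) == 30

    def test_correlated_triplet_pruned_to_low_vif(self):
        rng = np.random.default_rng(1)
        base = rng.binomial(2, 0.5, size=(500,)).astype(float)
        noisy = [np.clip(np.round(base + rng.normal(0, 0.45, 500)), 0, 2) for _ in range(2)]
        d = np.column_stack([base] + noisy + [rng.binomial(2, 0.5, 500)]).astype(float)
        g = make_geno(d)
        kept = ld_prune_vif(g, window=4, shift=2, vif_max=2.0)
        assert len(kept) < 4
        # retained set must satisfy the VIF bound by direct regression
        idx = [int(s[1:]) for s in kept]
        z = (d[:, idx] - d[:, idx].mean(0)) / d[:, idx].std(0)
        for col in range(len(idx)):
            others = np.delete(np.arange(len(idx)), col)
            if len(others) == 0:
                continue
            coef, *_ = np.linalg.lstsq(z[:, others], z[:, col], rcond=None)
            r2 = 1 - np.sum((z[:, col] - z[:, others] @ coef) ** 2) / np.sum(z[:, col] ** 2)
            assert 1.0 / (1.0 - r2) <= 2.0 + 1e-6

    def test_window_shift_contract(self):
        g = small_genotypes(seed=2, n=50, m=10)
        with pytest.raises(ValueError):
            ld_prune_vif(g, window=5, shift=6)


class TestMdsAndOutliers:
    def test_duplicate_individual_zero_distance(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(20, 50)).astype(float)
        d[1] = d[0]
        g = make_geno(d)
        sim = ibs_similarity(g)
        assert sim[0, 1] == pytest.approx(1.0)

    def test_population_split_on_first_component(self):
        cfg = SimulationConfig(
            n_individuals_pop=300, n_snps=400, n_causal=10,
            target_n_cases_1=1, target_n_cases_2=1, target_n_controls=1,
            fst_divergence=0.05, pop2_fraction=0.5, seed=11,
        )
        g = simulate_genotypes(cfg)
        comps = ibs_mds(g, n_components=10)
        labels = g.population_labels
        r = np.corrcoef(comps[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_homogeneous_cohort_no_outliers(self):
        g = small_genotypes(seed=3, n=200, m=300)
        comps = ibs_mds(g, n_components=10)
        assert len(detect_ancestry_outliers(comps, k_sd=6.0)) == 0

    def test_divergent_individuals_flagged(self):
        cfg = SimulationConfig(
            n_individuals_pop=150, n_snps=2000, n_causal=10,
            target_n_cases_1=1, target_n_cases_2=1, target_n_controls=1,
            fst_divergence=0.3, pop2_fraction=0.01, seed=5,
        )
        g = simulate_genotypes(cfg)
        outliers = detect_ancestry_outliers(ibs_mds(g, 10), k_sd=6.0)
        divergent = np.flatnonzero(g.population_labels == 1)
        assert set(outliers) == set(divergent)

    def test_infinite_k_sd_flags_nothing(self):
        comps = np.random.default_rng(0).normal(size=(50, 10))
        assert len(detect_ancestry_outliers(comps, k_sd=np.inf)) == 0

    def test_constant_component_skipped(self):
        comps = np.zeros((20, 10))
        assert len(detect_ancestry_outliers(comps, k_sd=2.0)) == 0


class TestIbdPihat:
    def test_duplicate_near_one_and_removed(self):
        g0 = small_genotypes(seed=6, n=40, m=2000)
        d = g0.dosages.copy()
        d[1] = d[0]
        g = make_geno(d)
        pihat = ibd_pihat(g)
        assert pihat[0, 1] > 0.9
        retained, pairs = ibd_pihat_filter(g, pihat_max=0.1)
        assert ("i0" in retained) != ("i1" in retained)

    def test_unrelated_near_zero(self):
        g = small_genotypes(seed=7, n=30, m=10000)
        pihat = ibd_pihat(g)
        off = pihat[np.triu_indices(30, k=1)]
        assert np.max(np.abs(off)) < 0.05 + 0.05  # clip at 0 makes this one-sided

    def test_parent_child_half(self):
        rng = np.random.default_rng(8)
        m = 10000
        p = rng.uniform(0.2, 0.5, m)
        hap = lambda: (rng.random((1, m)) < p).astype(float)
        father = hap() + hap()
        mother = hap() + hap()
        # child inherits one haplotype from each parent; share with father = 1 hap
        child = (rng.random(m) < father / 2).astype(float) + (rng.random(m) < mother / 2).astype(float)
        others = np.vstack([hap() + hap() for _ in range(20)])
        d = np.vstack([father, child, others])
        g = make_geno(d)
        pihat = ibd_pihat(g)
        assert pihat[0, 1] == pytest.approx(0.5, abs=0.05)


class TestPostImputation:
    def test_info_boundary(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(200, 2)).astype(float)
        g = make_geno(d)
        g.snps["info_score"] = [0.29, 0.31]
        out = post_imputation_filter(g)
        assert list(out.snps["snp"]) == ["s1"]

    def test_joint_grid_count_matches_direct(self):
        rng = np.random.default_rng(1)
        n, m = 400, 60
        d = rng.binomial(2, np.tile(np.linspace(0.002, 0.5, m), (n, 1))).astype(float)
        g = make_geno(d)
        info = np.tile([0.1, 0.5, 0.9], m // 3 + 1)[:m]
        g.snps["info_score"] = info
        out = post_imputation_filter(g)
        expect = int(np.sum((info > 0.3) & (g.maf() > 0.01)))
        assert out.n_snps == expect

    def test_missing_info_errors(self):
        g = small_genotypes(seed=1, n=30, m=5)
        with pytest.raises(ValueError, match="info_score"):
            post_imputation_filter(g)
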