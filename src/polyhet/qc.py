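"""Pre-analysis quality control for case-control genotype data.

Implements the standard GWAS QC ladder with the thresholds used throughout
this package: two-pass SNP missingness (5% then 2%), individual
heterozygosity (>15%) and missingness (>2%), MAF < 1%, Hardy-Weinberg exact
test (P < 5e-5, computed in controls), case/control differential
missingness (P < 1e-3), VIF-based LD pruning (window 100 / shift 50 /
VIF 2), identity-by-state MDS with ancestry-outlier exclusion on the top 10
components, and PLINK-style method-of-moments relatedness (PIHAT > 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "snp_qc_filter",
    "individual_qc_filter",
    "hwe_exact_test",
    "ld_prune_vif",
    "ibs_mds",
    "detect_ancestry_outliers",
    "ibd_pihat",
    "ibd_pihat_filter",
    "post_imputation_filter",
]

REASONS = (
    "snp_missing_pass1",
    "indiv_het",
    "indiv_missing",
    "snp_missing_pass2",
    "maf",
    "hwe",
    "diff_missing",
    "info_score",
    "post_imputation_maf",
    "relatedness",
    "ancestry_outlier",
)


@dataclass
class QCThresholds:
    """QC cutoffs; defaults are the pipeline's canonical values."""

    snp_missing_pass1: float = 0.05
    indiv_het_max: float = 0.15
    indiv_missing_max: float = 0.02
    snp_missing_pass2: float = 0.02
    maf_min: float = 0.01
    hwe_p_min: float = 5e-5
    diff_missing_p_min: float = 1e-3
    vif_window: int = 100
    vif_shift: int = 50
    vif_max: float = 2.0
    pihat_max: float = 0.1
    n_mds_components: int = 10
    outlier_k_sd: float = 6.0
    info_min: float = 0.3
    post_imputation_maf_min: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "snp_missing_pass1", "indiv_het_max", "indiv_missing_max",
            "snp_missing_pass2", "maf_min", "hwe_p_min", "diff_missing_p_min",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.vif_window >= self.vif_shift >= 1:
            raise ValueError("require vif_window >= vif_shift >= 1")


@dataclass
class Stage:
    name: str
    kind: str  # "snp" | "individual"
    n_before: int
    n_removed: int
    n_after: int
    removed_ids: List[str] = field(default_factory=list)


@dataclass
class QCReport:
    stages: List[Stage] = field(default_factory=list)

    def add(self, name: str, kind: str, before: int, removed_ids: Sequence[str]) -> None:
        if name not in REASONS:
            raise ValueError(f"unknown reason code {name!r}")
        self.stages.append(
            Stage(name, kind, before, len(removed_ids), before - len(removed_ids), list(removed_ids))
        )

    def telescopes(self) -> bool:
        """Counts must chain: after_k == before_k - removed_k, consecutively per kind."""
        last = {}
        for s in self.stages:
            if s.n_after != s.n_before - s.n_removed:
                return False
            if s.kind in last and s.n_before != last[s.kind]:
                return False
            last[s.kind] = s.n_after
        return True

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.kind, s.n_before, s.n_removed, s.n_after) for s in self.stages],
            columns=["stage", "kind", "n_before", "n_removed", "n_after"],
        )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than the observed one.
    Probabilities follow the standard recurrence in the heterozygote count.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts zero")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # heterozygote counts share the parity of the rare-allele count
    h_obs = n_Aa
    h_values = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(len(h_values))
    # start at mid-range het count and fill by recurrence both ways
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != n_rare % 2:
        mid += 1
    mid = min(max(mid, h_values[0]), n_rare)
    i_mid = int((mid - h_values[0]) // 2)
    probs[i_mid] = 1.0
    for i in range(i_mid, 0, -1):  # downward: P(h-2) from P(h)
        h = h_values[i]
        hom_r = (n_rare - h) / 2.0
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for i in range(i_mid, len(h_values) - 1):  # upward: P(h+2) from P(h)
        h = h_values[i]
        hom_r = (n_rare - h) / 2.0
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[int((h_obs - h_values[0]) // 2)]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_exact_pvalues(genotypes: GenotypeMatrix, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-SNP HWE exact p-values, optionally restricted to a sample subset."""
    d = genotypes.dosages if mask is None else genotypes.dosages[mask]
    out = np.ones(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            continue
        n_aa = int(np.sum(col == 0))  # A1 is 'A' here only by naming; counts are symmetric
        n_Aa = int(np.sum(col == 1))
        n_AA = int(np.sum(col == 2))
        out[j] = hwe_exact_test(n_AA, n_Aa, n_aa)
    return out


# ---------------------------------------------------------------------------
# SNP and individual filters

def _diff_missing_pvalues(genotypes: GenotypeMatrix, case_mask: np.ndarray) -> np.ndarray:
    """2x2 chi-square (no continuity correction) of missing x case status."""
    miss = np.isnan(genotypes.dosages)
    n_case = int(case_mask.sum())
    n_ctrl = int((~case_mask).sum())
    miss_case = miss[case_mask].sum(axis=0)
    miss_ctrl = miss[~case_mask].sum(axis=0)
    out = np.ones(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        table = np.array(
            [
                [miss_case[j], n_case - miss_case[j]],
                [miss_ctrl[j], n_ctrl - miss_ctrl[j]],
            ]
        )
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        out[j] = p
    return out


def snp_qc_filter(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> Tuple[GenotypeMatrix, QCReport]:
    """Run the staged SNP + individual QC ladder.

    Order: SNP missingness pass 1 (>5%) -> individual het/missingness ->
    SNP missingness pass 2 (>2%) -> MAF < 1% -> HWE exact P < 5e-5
    (controls only) -> differential missingness P < 1e-3. The report
    records each stage with removed ids.
    """
    if genotypes.n_snps == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")
    order = {s: i for i, s in enumerate(genotypes.samples)}
    ph = phenotypes.set_index("sample_id")
    if not set(genotypes.samples) <= set(ph.index):
        raise ValueError("phenotype/genotype misalignment")

    report = QCReport()
    g = genotypes

    # pass 1: gross SNP missingness
    keep = g.missing_rate_snp() <= thresholds.snp_missing_pass1
    report.add("snp_missing_pass1", "snp", g.n_snps, list(g.snps["snp"][~keep]))
    g = g.subset(snp_idx=np.flatnonzero(keep))

    # individual QC in between the two SNP passes
    g, ind_report = individual_qc_filter(g, thresholds)
    report.stages.extend(ind_report.stages)

    # pass 2: missingness, MAF, HWE (controls), differential missingness
    keep = g.missing_rate_snp() <= thresholds.snp_missing_pass2
    report.add("snp_missing_pass2", "snp", g.n_snps, list(g.snps["snp"][~keep]))
    g = g.subset(snp_idx=np.flatnonzero(keep))

    keep = g.maf() >= thresholds.maf_min
    report.add("maf", "snp", g.n_snps, list(g.snps["snp"][~keep]))
    g = g.subset(snp_idx=np.flatnonzero(keep))

    status = ph.loc[list(g.samples), "status"].to_numpy()
    ctrl_mask = status == 0
    hwe_mask = ctrl_mask if ctrl_mask.any() else np.ones(len(status), bool)
    p_hwe = hwe_exact_pvalues(g, mask=hwe_mask)
    keep = p_hwe >= thresholds.hwe_p_min
    report.add("hwe", "snp", g.n_snps, list(g.snps["snp"][~keep]))
    g = g.subset(snp_idx=np.flatnonzero(keep))

    if ctrl_mask.any() and (~ctrl_mask).any():
        p_dm = _diff_missing_pvalues(g, status == 1)
        keep = p_dm >= thresholds.diff_missing_p_min
        report.add("diff_missing", "snp", g.n_snps, list(g.snps["snp"][~keep]))
        g = g.subset(snp_idx=np.flatnonzero(keep))
    return g, report


def individual_qc_filter(
    genotypes: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> Tuple[GenotypeMatrix, QCReport]:
    """Remove individuals with heterozygosity > 15% or missingness > 2%.

    The heterozygosity rate is the proportion of non-missing calls equal
    to 1.
    """
    if genotypes.n_snps == 0:
        raise ValueError("no SNPs")
    report = QCReport()
    het = np.nansum(genotypes.dosages == 1, axis=1) / np.maximum(
        (~np.isnan(genotypes.dosages)).sum(axis=1), 1
    )
    keep = het <= thresholds.indiv_het_max
    report.add("indiv_het", "individual", genotypes.n_samples, list(genotypes.samples[~keep]))
    g = genotypes.subset(sample_idx=np.flatnonzero(keep))
    if g.n_samples == 0:
        raise ValueError("all individuals removed by heterozygosity filter")

    miss = g.missing_rate_sample()
    keep = miss <= thresholds.indiv_missing_max
    report.add("indiv_missing", "individual", g.n_samples, list(g.samples[~keep]))
    g = g.subset(sample_idx=np.flatnonzero(keep))
    if g.n_samples == 0:
        raise ValueError("all individuals removed by missingness filter")
    return g, report


# ---------------------------------------------------------------------------
# LD pruning

def _vif(standardized: np.ndarray, i: int, others: np.ndarray) -> float:
    """VIF of column i against the other columns: 1/(1-R^2) via least squares."""
    y = standardized[:, i]
    if len(others) == 0:
        return 1.0
    X = standardized[:, others]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def ld_prune_vif(
    genotypes: GenotypeMatrix,
    window: int = 100,
    shift: int = 50,
    vif_max: float = 2.0,
) -> List[str]:
    """Sliding-window VIF pruning; returns retained SNP ids.

    Within each window of ``window`` SNPs the SNP with the highest VIF
    (regression on the other retained SNPs of the window) is removed until
    all VIF <= ``vif_max``; the window slides by ``shift``. Ties remove the
    later SNP, keeping the first occurrence; the procedure is deterministic.
    """
    if window < shift:
        raise ValueError("window must be >= shift")
    d = genotypes.dosages
    col_mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_mean[None, :], d)
    sd = filled.std(axis=0)
    sd[sd == 0] = 1.0
    z = (filled - filled.mean(axis=0)) / sd
    removed = np.zeros(genotypes.n_snps, dtype=bool)
    chroms = genotypes.snps["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            while True:
                active = win[~removed[win]]
                if len(active) < 2:
                    break
                vifs = np.array([_vif(z, i, active[active != i]) for i in active])
                worst = np.max(vifs)
                if worst <= vif_max:
                    break
                # tie-break: remove the last of the argmax set (keep first SNP)
                removed[active[np.flatnonzero(vifs == worst)[-1]]] = True
            if start + window >= len(idx):
                break
            start += shift
    return list(genotypes.snps["snp"][~removed])


# ---------------------------------------------------------------------------
# IBS distances, MDS, ancestry outliers

def _genotype_indicators(genotypes: GenotypeMatrix):
    d = genotypes.dosages
    G = [(d == v).astype(float) for v in (0.0, 1.0, 2.0)]
    N = (~np.isnan(d)).astype(float)
    return G, N


def ibs_similarity(genotypes: GenotypeMatrix) -> np.ndarray:
    """Mean identity-by-state similarity, pairwise over non-missing SNPs.

    Per SNP the similarity of dosages ``x, y`` is ``1 - |x - y|/2``.
    """
    (G0, G1, G2), N = _genotype_indicators(genotypes)
    counts = N @ N.T
    # sum over SNPs of |x_i - x_j|: cross terms between genotype classes
    abs_diff = G0 @ G1.T + G1 @ G0.T + G1 @ G2.T + G2 @ G1.T + 2.0 * (G0 @ G2.T + G2 @ G0.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - abs_diff / (2.0 * counts)
    return sim


def ibs_mds(genotypes: GenotypeMatrix, n_components: int = 10) -> np.ndarray:
    """Classical MDS on 1 - IBS pairwise distances.

    Eigendecomposition of the double-centered squared-distance matrix;
    components are ordered by eigenvalue and scaled by sqrt(eigenvalue)
    (zeroed where eigenvalues are non-positive). Component signs are
    arbitrary.
    """
    n = genotypes.n_samples
    if n < n_components:
        raise ValueError("fewer individuals than requested components")
    dist = 1.0 - ibs_similarity(genotypes)
    np.fill_diagonal(dist, 0.0)
    d2 = dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    comps = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return comps


def detect_ancestry_outliers(mds_components: np.ndarray, k_sd: float = 6.0) -> np.ndarray:
    """Indices of individuals deviating > ``k_sd`` SDs on any top-10 component.

    Components with zero variance are skipped (never a division by zero).
    """
    comps = np.asarray(mds_components, dtype=float)[:, :10]
    if comps.shape[0] < 10:
        raise ValueError("need at least 10 individuals")
    if not np.isfinite(k_sd):
        return np.array([], dtype=int)
    mean = comps.mean(axis=0)
    sd = comps.std(axis=0)
    use = sd > 0
    if not use.any():
        return np.array([], dtype=int)
    z = np.abs(comps[:, use] - mean[use]) / sd[use]
    return np.flatnonzero((z > k_sd).any(axis=1))


# ---------------------------------------------------------------------------
# PLINK-style method-of-moments IBD

def ibd_pihat(genotypes: GenotypeMatrix) -> np.ndarray:
    """Pairwise PIHAT = P(IBD=2) + 0.5 P(IBD=1) by method of moments.

    Expected IBS-class counts given IBD state are computed from sample
    allele frequencies (monomorphic SNPs excluded); observed IBS counts are
    inverted PLINK-style and the resulting probabilities truncated to
    [0, 1]. With missing data the per-SNP expectations are scaled by the
    pair's coverage fraction.
    """
    p = genotypes.allele_freq()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for IBD estimation")
    g = genotypes.subset(snp_idx=np.flatnonzero(poly))
    p = p[poly]
    q = 1 - p
    (G0, G1, G2), N = _genotype_indicators(g)
    counts = N @ N.T
    ibs0 = G0 @ G2.T + G2 @ G0.T
    ibs2 = G0 @ G0.T + G1 @ G1.T + G2 @ G2.T
    ibs1 = counts - ibs0 - ibs2

    # per-SNP expected class probabilities given IBD state, summed over SNPs
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd1 = float(np.sum(p**3 + q**3 + p * q))
    m = g.n_snps
    frac = counts / m  # pair coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        P0 = ibs0 / (e0_ibd0 * frac)
        P1 = (ibs1 - P0 * e1_ibd0 * frac) / (e1_ibd1 * frac)
        P2 = (ibs2 - P0 * e2_ibd0 * frac - P1 * e2_ibd1 * frac) / (1.0 * frac * m)
    P0, P1, P2 = (np.clip(x, 0.0, 1.0) for x in (P0, P1, P2))
    pihat = np.clip(P2 + 0.5 * P1, 0.0, 1.0)
    return pihat


def ibd_pihat_filter(
    genotypes: GenotypeMatrix, pihat_max: float = 0.1
) -> Tuple[List[str], pd.DataFrame]:
    """Flag related pairs (PIHAT > cutoff) and greedily drop one member each.

    From each flagged pair the member with higher missingness is removed
    (ties: lexicographically larger id). Returns retained ids and the
    flagged-pair table.
    """
    pihat = ibd_pihat(genotypes)
    n = genotypes.n_samples
    iu = np.triu_indices(n, k=1)
    flagged = pihat[iu] > pihat_max
    pairs = pd.DataFrame(
        {
            "id1": genotypes.samples[iu[0][flagged]],
            "id2": genotypes.samples[iu[1][flagged]],
            "pihat": pihat[iu][flagged],
        }
    )
    miss = dict(zip(genotypes.samples, genotypes.missing_rate_sample()))
    removed = set()
    for _, row in pairs.sort_values(["pihat"], ascending=False).iterrows():
        a, b = row["id1"], row["id2"]
        if a in removed or b in removed:
            continue
        if miss[a] > miss[b]:
            removed.add(a)
        elif miss[b] > miss[a]:
            removed.add(b)
        else:
            removed.add(max(a, b))
    retained = [s for s in genotypes.samples if s not in removed]
    return retained, pairs


def post_imputation_filter(
    genotypes: GenotypeMatrix, info_min: float = 0.3, maf_min: float = 0.01
) -> GenotypeMatrix:
    """Retain SNPs with imputation info > ``info_min`` and MAF > ``maf_min``."""
    if "info_score" not in genotypes.snps.columns:
        raise ValueError("genotypes carry no info_score field")
    info = genotypes.snps["info_score"].to_numpy(dtype=float)
    if np.isnan(info).any():
        raise ValueError("info_score missing for some SNPs")
    keep = (info > info_min) & (genotypes.maf() > maf_min)
    return genotypes.subset(snp_idx=np.flatnonzero(keep))
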