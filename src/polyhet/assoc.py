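"""Association scans, fixed-effects meta-analysis and direction tests.

The per-SNP scan is a vectorised Newton (IRLS) logistic regression of
case status on allele dosage plus shared covariates, batched across SNPs;
it matches a conventional per-SNP maximum-likelihood fit to numerical
precision and reports Wald statistics. Meta-analysis is inverse-variance
fixed effects with Cochran's Q heterogeneity. Direction-of-effect
replication uses an exact binomial sign test on approximately independent
index SNPs.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import GenotypeMatrix, SignTestResult

__all__ = [
    "select_mds_covariates",
    "logistic_assoc_scan",
    "meta_analyze_fixed",
    "genomic_lambda",
    "select_index_snps",
    "sign_test",
    "genome_wide_regions",
    "align_alleles",
    "AMBIGUOUS_PAIRS",
]

#: strand-ambiguous allele pairs dropped at alignment
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_CHI1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


def select_mds_covariates(
    mds_components: np.ndarray, phenotype: np.ndarray, alpha: float = 0.05
) -> List[int]:
    """Indices of top-10 MDS components significantly associated with phenotype.

    Each component is tested in its own logistic regression of status on
    that single component.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("constant phenotype")
    comps = np.atleast_2d(np.asarray(mds_components, dtype=float))
    selected = []
    for k in range(min(10, comps.shape[1])):
        X = sm.add_constant(comps[:, k])
        try:
            fit = sm.Logit(y, X).fit(disp=0)
            p = float(fit.pvalues[1])
        except Exception:
            continue
        if p < alpha:
            selected.append(k)
    return selected


def _batched_logistic(
    dosages: np.ndarray,
    y: np.ndarray,
    covariates: Optional[np.ndarray],
    max_iter: int = 25,
    tol: float = 1e-10,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton-Raphson logistic fits for many SNPs sharing covariates.

    Returns (beta, se, ok) for the dosage coefficient. Non-converged or
    separated fits have ok=False.
    """
    n, B = dosages.shape[1], dosages.shape[0]
    C = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    k = C.shape[1] + 1
    beta = np.zeros((B, k))
    beta[:, 0] = np.log(np.mean(y) / (1 - np.mean(y)))  # intercept at logit prevalence
    ok = np.ones(B, dtype=bool)
    converged = np.zeros(B, dtype=bool)
    for _ in range(max_iter):
        eta = beta[:, :-1] @ C.T + beta[:, -1:] * dosages  # (B, n)
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1 - mu)
        resid = y[None, :] - mu
        # score: X' (y - mu), per SNP
        g_cov = resid @ C                      # (B, k-1)
        g_dos = np.sum(resid * dosages, 1)     # (B,)
        grad = np.column_stack([g_cov, g_dos])
        # information: X' W X in blocks
        I_cc = np.einsum("bn,ni,nj->bij", w, C, C)
        I_cd = np.einsum("bn,ni,bn->bi", w, C, dosages)
        I_dd = np.sum(w * dosages**2, axis=1)
        info = np.empty((B, k, k))
        info[:, :-1, :-1] = I_cc
        info[:, :-1, -1] = I_cd
        info[:, -1, :-1] = I_cd
        info[:, -1, -1] = I_dd
        try:
            delta = np.linalg.solve(info, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # singular information for some SNPs: solve individually
            delta = np.zeros_like(grad)
            for b in range(B):
                try:
                    delta[b] = np.linalg.solve(info[b], grad[b])
                except np.linalg.LinAlgError:
                    ok[b] = False
        delta = np.clip(delta, -10, 10)
        beta = beta + delta
        newly = np.max(np.abs(delta), axis=1) < tol
        converged |= newly
        if converged.all():
            break
    # Wald SE of the dosage term from the final information matrix
    se = np.full(B, np.nan)
    with np.errstate(invalid="ignore"):
        for b in range(B):
            if not ok[b]:
                continue
            try:
                cov = np.linalg.inv(info[b])
                se[b] = np.sqrt(cov[-1, -1])
            except np.linalg.LinAlgError:
                ok[b] = False
    # separation heuristics: runaway effect or exploding SE
    ok &= converged & np.isfinite(se) & (np.abs(beta[:, -1]) < 25) & (se < 1e3)
    return beta[:, -1], se, ok


def logistic_assoc_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    chunk_size: int = 2048,
) -> pd.DataFrame:
    """Per-SNP logistic GWAS: status ~ dosage + covariates, Wald tests.

    Missing dosages are mean-imputed within SNP. Monomorphic or separated
    SNPs yield NA results with a reason code instead of failing the scan.
    Returns a summary-statistics frame (SNP, CHR, BP, A1, A2, FRQ, BETA,
    SE, P, N, REASON) with A1 the effect (counted) allele.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    n, m = genotypes.n_samples, genotypes.n_snps
    if len(y) != n:
        raise ValueError("phenotype length mismatch")
    freq = genotypes.allele_freq()
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    reason = np.array(["ok"] * m, dtype=object)

    mono = (freq <= 0) | (freq >= 1) | ~np.isfinite(freq)
    todo = np.flatnonzero(~mono)
    reason[mono] = "monomorphic"
    for start in range(0, len(todo), chunk_size):
        idx = todo[start : start + chunk_size]
        d = genotypes.dosages[:, idx].T.copy()  # (B, n)
        nanmask = np.isnan(d)
        if nanmask.any():
            fill = np.where(nanmask, (2 * freq[idx])[:, None], 0.0)
            d = np.where(nanmask, fill, d)
        b, s, ok = _batched_logistic(d, y, covariates)
        beta[idx] = np.where(ok, b, np.nan)
        se[idx] = np.where(ok, s, np.nan)
        reason[idx[~ok]] = "no_convergence"
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
        p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "SNP": genotypes.snps["snp"].to_numpy(),
            "CHR": genotypes.snps["chrom"].to_numpy(),
            "BP": genotypes.snps["pos"].to_numpy(),
            "A1": genotypes.snps["a1"].to_numpy(),
            "A2": genotypes.snps["a2"].to_numpy(),
            "FRQ": freq,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
            "REASON": reason,
        }
    )
    if "info_score" in genotypes.snps.columns:
        out["INFO"] = genotypes.snps["info_score"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# allele alignment and meta-analysis

def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> np.ndarray:
    pairs = list(zip(a1.astype(str), a2.astype(str)))
    return np.array([p in AMBIGUOUS_PAIRS for p in pairs])


def align_alleles(reference: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Harmonize ``other`` onto the reference effect allele.

    Matching A1/A2 keeps the row; swapped alleles flip the sign of BETA
    (and 1-FRQ); strand-ambiguous (A/T, C/G) and otherwise incompatible
    SNPs are dropped.
    """
    ref = reference[["SNP", "A1", "A2"]].rename(columns={"A1": "refA1", "A2": "refA2"})
    merged = other.merge(ref, on="SNP", how="inner")
    amb = _is_ambiguous(merged["refA1"], merged["refA2"]) | _is_ambiguous(
        merged["A1"], merged["A2"]
    )
    same = (merged["A1"] == merged["refA1"]) & (merged["A2"] == merged["refA2"])
    swap = (merged["A1"] == merged["refA2"]) & (merged["A2"] == merged["refA1"])
    keep = (same | swap) & ~amb
    merged = merged[keep].copy()
    flip = swap[keep].to_numpy()
    merged.loc[flip, "BETA"] = -merged.loc[flip, "BETA"]
    if "FRQ" in merged.columns:
        merged.loc[flip, "FRQ"] = 1.0 - merged.loc[flip, "FRQ"]
    merged["A1"] = merged.pop("refA1")
    merged["A2"] = merged.pop("refA2")
    return merged


def meta_analyze_fixed(studies: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effects meta-analysis with Cochran's Q.

    Studies are aligned to the first study's effect alleles (sign flips for
    swapped coding, ambiguous SNPs dropped). Per SNP: weights ``w=1/se^2``,
    pooled beta ``sum(w b)/sum(w)``, pooled se ``1/sqrt(sum w)``,
    ``Q = sum w (b - b_pooled)^2`` with heterogeneity p from chi-square on
    k-1 df, and a +/-/? direction string across studies.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    ref = studies[0]
    aligned = [ref[~_is_ambiguous(ref["A1"], ref["A2"])].copy()]
    aligned += [align_alleles(ref, s) for s in studies[1:]]
    common = set(aligned[0]["SNP"])
    for s in aligned[1:]:
        common &= set(s["SNP"])
    if not common:
        raise ValueError("no overlapping SNPs after alignment")
    frames = [
        s[s["SNP"].isin(common)].dropna(subset=["BETA", "SE"]).set_index("SNP").sort_index()
        for s in aligned
    ]
    snps = sorted(set.intersection(*(set(f.index) for f in frames)))
    k = len(frames)
    betas = np.column_stack([f.loc[snps, "BETA"].to_numpy(dtype=float) for f in frames])
    ses = np.column_stack([f.loc[snps, "SE"].to_numpy(dtype=float) for f in frames])
    w = 1.0 / ses**2
    # center on the first study so identical studies pool to beta_1 exactly
    # (and Q is exactly zero), independent of summation rounding
    ref_beta = betas[:, 0]
    pooled = ref_beta + np.sum(w * (betas - ref_beta[:, None]), axis=1) / np.sum(w, axis=1)
    pooled_se = 1.0 / np.sqrt(np.sum(w, axis=1))
    Q = np.sum(w * (betas - pooled[:, None]) ** 2, axis=1)
    p_het = stats.chi2.sf(Q, df=k - 1)
    p = 2 * stats.norm.sf(np.abs(pooled / pooled_se))
    direction = ["".join("+" if b > 0 else "-" if b < 0 else "?" for b in row) for row in betas]
    meta = pd.DataFrame(
        {
            "SNP": snps,
            "BETA": pooled,
            "SE": pooled_se,
            "P": p,
            "Q": Q,
            "HET_P": p_het,
            "K": k,
            "DIRECTION": direction,
        }
    )
    pos = frames[0][["CHR", "BP", "A1", "A2"]]
    meta = meta.merge(pos, left_on="SNP", right_index=True, how="left")
    return meta[["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "Q", "HET_P", "K", "DIRECTION"]]


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square over 0.4549.

    Reported at 3-decimal precision, per convention.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no valid p-values")
    chi = stats.chi2.isf(p, df=1)
    return float(np.round(np.median(chi) / _CHI1_MEDIAN, 3))


def select_index_snps(
    summary: pd.DataFrame,
    p_threshold: float,
    r2_max: float = 0.1,
    window_kb: float = 500.0,
    genotypes_reference: Optional[GenotypeMatrix] = None,
) -> List[str]:
    """Greedy selection of approximately independent association signals.

    Take the most significant remaining SNP below ``p_threshold``, drop all
    SNPs within ``window_kb`` whose reference-panel r^2 with it exceeds
    ``r2_max``, repeat. Without a reference panel only the p-value
    threshold applies (appropriate for linkage-equilibrium data).
    """
    sig = summary.dropna(subset=["P"])
    sig = sig[sig["P"] < p_threshold].sort_values("P")
    if len(sig) == 0:
        return []
    if genotypes_reference is None:
        return list(sig["SNP"])
    ref_idx = {s: i for i, s in enumerate(genotypes_reference.snps["snp"])}
    d = genotypes_reference.dosages
    mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), mean[None, :], d)
    remaining = sig.reset_index(drop=True)
    chosen: List[str] = []
    while len(remaining):
        top = remaining.iloc[0]
        chosen.append(str(top["SNP"]))
        near = (remaining["CHR"] == top["CHR"]) & (
            (remaining["BP"] - top["BP"]).abs() <= window_kb * 1000
        )
        drop = np.zeros(len(remaining), dtype=bool)
        drop[0] = True
        if top["SNP"] in ref_idx:
            x = filled[:, ref_idx[top["SNP"]]]
            for i in np.flatnonzero(near.to_numpy()):
                snp = remaining.iloc[i]["SNP"]
                if snp in ref_idx and snp != top["SNP"]:
                    yv = filled[:, ref_idx[snp]]
                    if np.std(yv) == 0 or np.std(x) == 0:
                        r2 = 1.0
                    else:
                        r2 = float(np.corrcoef(x, yv)[0, 1]) ** 2
                    if r2 > r2_max:
                        drop[i] = True
        remaining = remaining[~drop].reset_index(drop=True)
    return chosen


def sign_test(
    discovery_index: pd.DataFrame,
    target: pd.DataFrame,
    thresholds: Sequence[float] = (1e-3, 1e-4, 1e-5, 1e-6),
) -> Dict[float, SignTestResult]:
    """Direction-of-effect concordance of discovery index SNPs in a target.

    At each discovery p-value cutoff, count index SNPs whose aligned effect
    has the same sign in the target; test against 0.5 with a two-sided
    exact binomial. Index SNPs absent from the target are excluded and
    counted.
    """
    aligned = align_alleles(discovery_index, target)
    merged = discovery_index.merge(
        aligned[["SNP", "BETA"]].rename(columns={"BETA": "BETA_T"}), on="SNP", how="left"
    )
    out: Dict[float, SignTestResult] = {}
    for thr in thresholds:
        sub = merged[merged["P"] < thr]
        missing = int(sub["BETA_T"].isna().sum())
        sub = sub.dropna(subset=["BETA_T"])
        n = len(sub)
        conc = int(np.sum(np.sign(sub["BETA"]) == np.sign(sub["BETA_T"])))
        if n > 0:
            pval = float(stats.binomtest(conc, n, 0.5, alternative="two-sided").pvalue)
        else:
            pval = float("nan")
        out[thr] = SignTestResult(
            threshold=float(thr),
            n_index_snps=n,
            n_concordant=conc,
            proportion_concordant=conc / n if n else float("nan"),
            binomial_p_two_sided=pval,
            n_missing_in_target=missing,
        )
    return out


def genome_wide_regions(
    meta: pd.DataFrame, alpha: float = 5e-8, merge_kb: float = 250.0
) -> pd.DataFrame:
    """Merge genome-wide-significant SNPs into regions.

    Significant SNPs on the same chromosome within ``merge_kb`` of each
    other join one region; each region reports its index SNP (minimum p),
    bounds and SNP count.
    """
    sig = meta.dropna(subset=["P"])
    sig = sig[sig["P"] < alpha].sort_values(["CHR", "BP"])
    regions = []
    for chrom, grp in sig.groupby("CHR", sort=True):
        bp = grp["BP"].to_numpy()
        breaks = np.flatnonzero(np.diff(bp) > merge_kb * 1000)
        bounds = np.split(np.arange(len(grp)), breaks + 1)
        for b in bounds:
            block = grp.iloc[b]
            top = block.loc[block["P"].idxmin()]
            regions.append(
                {
                    "CHR": chrom,
                    "START": int(block["BP"].min()),
                    "END": int(block["BP"].max()),
                    "N_SNPS": int(len(block)),
                    "INDEX_SNP": top["SNP"],
                    "INDEX_P": float(top["P"]),
                }
            )
    return pd.DataFrame(regions, columns=["CHR", "START", "END", "N_SNPS", "INDEX_SNP", "INDEX_P"])
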