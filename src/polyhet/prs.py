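"""Polygenic risk scoring and covariate-adjusted Nagelkerke delta-R2 tests.

Scores are sums of risk-allele dosages weighted by discovery effect sizes
over SNPs passing each p-value threshold; the predictive increment is the
Nagelkerke pseudo-R2 of a logistic model with score plus covariates minus
that of the covariates alone.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assoc import AMBIGUOUS_PAIRS
from .types import GenotypeMatrix, PrsTestResult, ScoreProfile

__all__ = [
    "DEFAULT_THRESHOLDS",
    "compute_scores",
    "nagelkerke_r2",
    "nagelkerke_delta_r2",
    "prs_case_control_test",
    "prs_case_case_test",
]

DEFAULT_THRESHOLDS = (0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


def _align_discovery_to_target(
    target: GenotypeMatrix, discovery: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match discovery SNPs to target columns on the discovery effect allele.

    Returns (target column indices, weights-orientation sign-corrected
    dosage matrix is *not* built here; instead) the per-SNP flip flags and
    the discovery rows kept. Strand-ambiguous and allele-incompatible SNPs
    are dropped.
    """
    meta = target.snps
    tgt = meta.reset_index().rename(columns={"index": "_col"})
    merged = discovery.merge(
        tgt[["_col", "snp", "a1", "a2"]], left_on="SNP", right_on="snp", how="inner"
    )
    amb = np.array(
        [
            (str(a), str(b)) in AMBIGUOUS_PAIRS
            for a, b in zip(merged["A1"], merged["A2"])
        ],
        dtype=bool,
    )
    same = (merged["A1"] == merged["a1"]) & (merged["A2"] == merged["a2"])
    swap = (merged["A1"] == merged["a2"]) & (merged["A2"] == merged["a1"])
    keep = (same | swap) & ~amb
    merged = merged[keep]
    return (
        merged["_col"].to_numpy(dtype=int),
        swap[keep].to_numpy(),
        merged.reset_index(drop=True),
    )


def compute_scores(
    target: GenotypeMatrix,
    discovery: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    weighting: str = "logodds",
) -> ScoreProfile:
    """Effect-weighted risk-allele scores at each p-value cutoff.

    Dosages are aligned to the discovery effect allele (``2 - x`` when the
    target coding is swapped); weights are the discovery log-odds (default)
    or 1 (``unit`` mode, risk-allele counting with the risk allele defined
    by a positive discovery beta). Missing dosages are imputed as twice the
    target allele frequency.
    """
    if weighting not in ("logodds", "unit"):
        raise ValueError("weighting must be 'logodds' or 'unit'")
    cols, flip, disc = _align_discovery_to_target(target, discovery)
    if len(cols) == 0:
        raise ValueError("no alignable SNPs between discovery and target")
    d = target.dosages[:, cols]
    freq = target.allele_freq()[cols]
    d = np.where(np.isnan(d), (2 * freq)[None, :], d)
    d = np.where(flip[None, :], 2.0 - d, d)
    beta = disc["BETA"].to_numpy(dtype=float)
    if weighting == "unit":
        # count risk alleles: orient each SNP to its risk direction
        d = np.where((beta < 0)[None, :], 2.0 - d, d)
        w = np.ones_like(beta)
    else:
        w = beta
    pvals = disc["P"].to_numpy(dtype=float)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    scores = np.zeros((target.n_samples, len(thresholds)))
    n_used = np.zeros(len(thresholds), dtype=int)
    for i, t in enumerate(thresholds):
        mask = pvals < t
        n_used[i] = int(mask.sum())
        if n_used[i]:
            scores[:, i] = d[:, mask] @ w[mask]
    return ScoreProfile(
        sample_ids=target.samples.copy(),
        thresholds=thresholds,
        scores=scores,
        n_snps_used=n_used,
    )


def _logit_ll(y: np.ndarray, X: Optional[np.ndarray]) -> Tuple[float, object]:
    Xd = np.ones((len(y), 1)) if X is None else sm.add_constant(X)
    fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    return float(fit.llf), fit


def nagelkerke_r2(phenotype: np.ndarray, X: Optional[np.ndarray]) -> float:
    """Nagelkerke pseudo-R2 of a logistic model against the intercept-only null."""
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    ll1, _ = _logit_ll(y, X)
    ll0, _ = _logit_ll(y, None)
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    max_r2 = 1.0 - np.exp((2.0 / n) * ll0)
    return float(cox_snell / max_r2)


def nagelkerke_delta_r2(
    phenotype: np.ndarray, score: np.ndarray, covariates: Optional[np.ndarray] = None
) -> float:
    """R2_N(covariates + score) - R2_N(covariates alone).

    With no covariates the baseline model is intercept-only (R2_N = 0), so
    the delta is the score's full Nagelkerke R2.
    """
    y = np.asarray(phenotype, dtype=float)
    s = np.asarray(score, dtype=float).reshape(-1, 1)
    if np.std(s) == 0:
        return 0.0
    full = s if covariates is None else np.column_stack([covariates, s])
    r2_full = nagelkerke_r2(y, full)
    r2_base = 0.0 if covariates is None else nagelkerke_r2(y, covariates)
    return float(r2_full - r2_base)


def _prs_regression(
    y: np.ndarray,
    score: np.ndarray,
    covariates: Optional[np.ndarray],
    threshold: float,
    labels: Tuple[str, str],
) -> PrsTestResult:
    s = np.asarray(score, dtype=float)
    if np.std(s) > 0:
        s_std = (s - s.mean()) / s.std()
        X = s_std.reshape(-1, 1) if covariates is None else np.column_stack([covariates, s_std])
        ll, fit = _logit_ll(y, X)
        t = float(fit.params[-1] / fit.bse[-1])
        p = float(fit.pvalues[-1])
        dr2 = nagelkerke_delta_r2(y, s, covariates)
    else:
        t, p, dr2 = 0.0, 1.0, 0.0
    direction = labels[1] if t > 0 else labels[0]
    return PrsTestResult(
        threshold=float(threshold),
        t_statistic=t,
        p_value=p,
        delta_nagelkerke_r2=dr2,
        direction=direction,
        n_group_1=int(np.sum(y == 1)),
        n_group_0=int(np.sum(y == 0)),
    )


def prs_case_control_test(
    scores: ScoreProfile,
    phenotypes: pd.DataFrame,
    covariates: Optional[np.ndarray] = None,
) -> Dict[float, PrsTestResult]:
    """Logistic regression of case status on score (+ covariates) per cutoff.

    ``direction`` reports which group carries the higher scores ("case"
    when the score coefficient is positive).
    """
    ph = phenotypes.set_index("sample_id").loc[list(scores.sample_ids)]
    y = ph["status"].to_numpy(dtype=float)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both cases and controls required")
    out = {}
    for i, thr in enumerate(scores.thresholds):
        out[float(thr)] = _prs_regression(
            y, scores.scores[:, i], covariates, thr, labels=("control", "case")
        )
    return out


def prs_case_case_test(
    scores: ScoreProfile,
    phenotypes: pd.DataFrame,
    subtype_a: str,
    subtype_b: str,
    covariates: Optional[np.ndarray] = None,
) -> Dict[float, PrsTestResult]:
    """Subtype-contrast scoring test: membership of ``subtype_b`` vs ``subtype_a``.

    ``direction`` names the subtype with the higher scores.
    """
    ph = phenotypes.set_index("sample_id").loc[list(scores.sample_ids)]
    mask = ph["subtype"].isin([subtype_a, subtype_b]).to_numpy()
    if not mask.any():
        raise ValueError("no individuals in the requested subtypes")
    sub = ph[mask]
    y = (sub["subtype"] == subtype_b).to_numpy(dtype=float)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("both subtypes must be non-empty")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float).reshape(len(ph), -1)[mask]
    out = {}
    for i, thr in enumerate(scores.thresholds):
        out[float(thr)] = _prs_regression(
            y, scores.scores[mask, i], cov, thr, labels=(subtype_a, subtype_b)
        )
    return out
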