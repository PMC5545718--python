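"""Core in-memory containers shared across the pipeline.

Genotypes are held as an individuals x SNPs matrix of additive dosages
(counts of the A1 allele, ``numpy.nan`` for missing calls) with a pandas
frame of per-SNP metadata. Phenotypes are a plain :class:`pandas.DataFrame`
with a fixed schema validated by :func:`validate_phenotypes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("BD1", "BD2", "SAB", "none")

#: required columns of a phenotype table
PHENO_COLUMNS = ("sample_id", "status", "subtype", "site")


@dataclass
class GenotypeMatrix:
    """Additive genotype dosages with per-SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array of A1-allele counts in
        ``{0, 1, 2}``; missing calls are ``nan``.
    snps
        Per-SNP metadata with at least columns ``snp``, ``chrom``, ``pos``,
        ``a1``, ``a2``; optional ``info_score``, ``imputation_r2`` and (for
        simulated data) ``p_true``, the generative A1 frequency.
    samples
        Ordered, unique sample identifiers.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = np.asarray(self.samples, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if n == 0 or m == 0:
            raise ValueError("empty genotype matrix")
        if len(self.samples) != n:
            raise ValueError("sample count does not match dosage rows")
        if len(self.snps) != m:
            raise ValueError("SNP metadata does not match dosage columns")
        if self.snps["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if pd.Series(self.samples).duplicated().any():
            raise ValueError("duplicate sample ids")
        self.snps = self.snps.reset_index(drop=True)
        # positions must be sorted within each chromosome (bim convention)
        for _, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError("positions not non-decreasing within chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Sample frequency of the A1 allele per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate_snp(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def missing_rate_sample(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def subset(
        self,
        sample_idx: Optional[np.ndarray] = None,
        snp_idx: Optional[np.ndarray] = None,
    ) -> "GenotypeMatrix":
        """Row/column subset preserving metadata alignment."""
        d = self.dosages
        s = self.samples
        meta = self.snps
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx]
            s = s[sample_idx]
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            d = d[:, snp_idx]
            meta = meta.iloc[snp_idx]
        return GenotypeMatrix(d.copy(), meta.reset_index(drop=True).copy(), s.copy())

    def subset_samples_by_id(self, ids: Sequence) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([lookup[i] for i in ids], dtype=int)
        return self.subset(sample_idx=idx)


def validate_phenotypes(pheno: pd.DataFrame, genotypes: Optional[GenotypeMatrix] = None) -> pd.DataFrame:
    """Check the phenotype-table schema and (optionally) genotype alignment.

    ``status`` is coded 0=control, 1=case; ``subtype`` must be ``none``
    exactly for controls.
    """
    for col in PHENO_COLUMNS:
        if col not in pheno.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    if pheno["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    if not set(pheno["status"].unique()) <= {0, 1}:
        raise ValueError("status must be coded 0=control, 1=case")
    if not set(pheno["subtype"].unique()) <= set(SUBTYPES):
        raise ValueError(f"subtype must be one of {SUBTYPES}")
    ctrl = pheno["status"] == 0
    if ((pheno["subtype"] == "none") != ctrl).any():
        raise ValueError("subtype must be 'none' iff status is control")
    if genotypes is not None:
        geno_ids = set(genotypes.samples)
        missing = set(pheno["sample_id"]) - geno_ids
        if missing:
            raise ValueError(f"{len(missing)} phenotype samples absent from genotypes")
    return pheno


@dataclass
class GRM:
    """Genetic relationship matrix with per-pair SNP counts."""

    values: np.ndarray          # (n, n) symmetric
    n_snps_used: np.ndarray     # (n, n) int, SNPs non-missing in both members
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GRM has non-finite entries")
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, ids: Sequence) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[i] for i in ids], dtype=int)
        return self.values[np.ix_(idx, idx)]


@dataclass
class VarianceComponents:
    """Univariate REML fit: y = Xb + g + e with V = sg2*A + se2*I."""

    sigma_g2: float
    sigma_e2: float
    sampling_covariance: np.ndarray  # 2x2, inverse average-information
    log_likelihood: float
    n_iterations: int
    converged: bool

    @property
    def h2_observed(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else 0.0

    @property
    def se_h2_observed(self) -> float:
        """Delta-method SE of sg2/(sg2+se2)."""
        tot = self.sigma_g2 + self.sigma_e2
        if tot <= 0:
            return float("nan")
        grad = np.array([self.sigma_e2, -self.sigma_g2]) / tot**2
        var = float(grad @ self.sampling_covariance @ grad)
        return float(np.sqrt(max(var, 0.0)))


@dataclass
class BivariateComponents:
    """Bivariate REML fit over two disjoint individual sets."""

    sigma_g2_1: float
    sigma_g2_2: float
    sigma_g12: float
    sigma_e2_1: float
    sigma_e2_2: float
    sampling_covariance: np.ndarray  # 5x5 in order (g1, g12, g2, e1, e2)
    log_likelihood: float
    n_iterations: int
    converged: bool


@dataclass
class HeritabilityEstimate:
    """Observed-scale h2 and its liability-scale transformation."""

    h2_observed: float
    se_observed: float
    h2_liability: float
    se_liability: float
    prevalence_K: float
    case_proportion_P: float
    z_density: float


@dataclass
class GeneticCorrelationEstimate:
    rg: float
    se_rg: float
    source: str = "subtype_pair"  # or "mixed_pair"


@dataclass
class SignTestResult:
    threshold: float
    n_index_snps: int
    n_concordant: int
    proportion_concordant: float
    binomial_p_two_sided: float
    n_missing_in_target: int = 0


@dataclass
class ScoreProfile:
    """Per-individual polygenic scores at an ordered grid of p-value cutoffs."""

    sample_ids: np.ndarray
    thresholds: np.ndarray          # ordered ascending
    scores: np.ndarray              # (n_samples, n_thresholds)
    n_snps_used: np.ndarray         # (n_thresholds,)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=[f"pT_{t:g}" for t in self.thresholds])
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class PrsTestResult:
    threshold: float
    t_statistic: float
    p_value: float
    delta_nagelkerke_r2: float
    direction: str
    n_group_1: int
    n_group_0: int


@dataclass
class SplitPlan:
    """One unit of the control-splitting / case-mixing permutation design."""

    permutation_index: int
    control_group_A: np.ndarray
    control_group_B: np.ndarray
    case_group_1: np.ndarray
    case_group_2: np.ndarray
    kind: str  # "subtype_pair" | "mixed_pair"
    seed_state: int

    def validate(self) -> None:
        a, b = set(self.control_group_A), set(self.control_group_B)
        if a & b:
            raise ValueError("control halves overlap")
        if abs(len(a) - len(b)) > 1:
            raise ValueError("control halves differ by more than 1")
        if set(self.case_group_1) & set(self.case_group_2):
            raise ValueError("case groups overlap")


@dataclass
class RgDistributions:
    """Collected genetic-correlation estimates of the permutation contrast."""

    rg_subtype: np.ndarray
    rg_mix: np.ndarray
    converged_subtype: np.ndarray
    converged_mix: np.ndarray

    def summary(self) -> dict:
        out = {}
        for name, vals, conv in (
            ("subtype", self.rg_subtype, self.converged_subtype),
            ("mix", self.rg_mix, self.converged_mix),
        ):
            v = np.asarray(vals, dtype=float)[np.asarray(conv, dtype=bool)]
            out[name] = {
                "n": int(len(vals)),
                "n_converged": int(len(v)),
                "mean": float(np.mean(v)) if len(v) else float("nan"),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
                "min": float(np.min(v)) if len(v) else float("nan"),
                "max": float(np.max(v)) if len(v) else float("nan"),
            }
        return out
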