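"""Synthetic case-control cohorts under a two-subtype liability-threshold model.

The generator emulates the study design the rest of the package analyses:
biallelic autosomal genotypes in Hardy-Weinberg proportions, two disease
subtypes whose per-SNP causal effects are correlated at a configurable
``rho_effects``, population prevalences near 0.6% and 0.4%, and case-control
ascertainment to target counts spread over collection sites.

Each stage draws from its own deterministic child of the config seed, so a
config fully determines every downstream artefact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, validate_phenotypes

__all__ = [
    "SimulationConfig",
    "TrueEffects",
    "simulate_genotypes",
    "simulate_subtype_effects",
    "assign_liability_phenotypes",
    "ascertain_cohort",
    "simulate_cohort",
    "inject_missingness",
    "attach_info_scores",
]


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent, reproducible stream for a pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


@dataclass
class SimulationConfig:
    """Generative truth for a two-subtype liability-threshold cohort.

    Defaults mirror the study conditions this package targets: lifetime
    prevalences of 0.6% (subtype 1, BD I-like) and 0.4% (subtype 2,
    BD II-like), liability-scale heritabilities 0.35 and 0.25, causal effects
    correlated at 0.78, and ascertained case groups of 2811 / 1398 with
    11164 shared controls drawn from four collection sites. Desk-scale
    analyses pass smaller targets explicitly.
    """

    n_individuals_pop: int = 600_000
    n_snps: int = 10_000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_causal: int = 1_000
    h2_liab_1: float = 0.35
    h2_liab_2: float = 0.25
    rho_effects: float = 0.78
    prevalence_1: float = 0.006
    prevalence_2: float = 0.004
    target_n_cases_1: int = 2811
    target_n_cases_2: int = 1398
    target_n_controls: int = 11164
    n_sites: int = 4
    site_mixing: Optional[np.ndarray] = None  # (n_sites, 3) weights for (BD1, BD2, control)
    seed: int = 0
    # optional structure switches (off by default: clean, unlinked, one population)
    ld_block_size: int = 1          # >1 turns on autoregressive haplotype blocks
    ld_rho: float = 0.0             # within-block haplotype correlation
    fst_divergence: float = 0.0     # Balding-Nichols divergence of a second population
    pop2_fraction: float = 0.0      # fraction of individuals drawn from it

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if min(self.n_individuals_pop, self.n_snps) <= 0:
            raise ValueError("population size and SNP count must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValueError("n_causal must be in [0, n_snps]")
        for h2 in (self.h2_liab_1, self.h2_liab_2):
            if not 0 <= h2 <= 1:
                raise ValueError("heritabilities must be in [0, 1]")
        if abs(self.rho_effects) > 1:
            raise ValueError("|rho_effects| must be <= 1")
        for k in (self.prevalence_1, self.prevalence_2):
            if not 0 < k < 1:
                raise ValueError("prevalences must be in (0, 1)")
        if self.prevalence_1 + self.prevalence_2 >= 1:
            raise ValueError("prevalences must sum to < 1")
        if self.site_mixing is not None:
            sm = np.asarray(self.site_mixing, dtype=float)
            if sm.shape != (self.n_sites, 3):
                raise ValueError("site_mixing must have shape (n_sites, 3)")
            if np.any(sm < 0) or np.any(sm.sum(axis=0) <= 0):
                raise ValueError("site_mixing weights must be non-negative with positive column sums")
            self.site_mixing = sm


@dataclass
class TrueEffects:
    """Generative per-SNP standardized effects for the two subtype liabilities."""

    causal_indices: np.ndarray
    beta_1: np.ndarray
    beta_2: np.ndarray


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw unlinked biallelic genotypes at Hardy-Weinberg proportions.

    Per-SNP A1 frequencies are uniform on ``maf_range`` and recorded in the
    SNP metadata as ``p_true``. With ``ld_block_size > 1`` haplotypes within a
    block share an AR(1) latent Gaussian at correlation ``ld_rho`` (used only
    to exercise LD pruning); with ``pop2_fraction > 0`` a second population
    with Balding-Nichols frequency divergence ``fst_divergence`` is mixed in.
    """
    rng = _stage_rng(config.seed, 0)
    n, m = config.n_individuals_pop, config.n_snps
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    n2 = int(round(n * config.pop2_fraction))
    n1 = n - n2
    pops = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    if n2 > 0 and config.fst_divergence > 0:
        f = config.fst_divergence
        a, b = p * (1 - f) / f, (1 - p) * (1 - f) / f
        p2 = rng.beta(a, b)
    else:
        p2 = p

    if config.ld_block_size <= 1 or config.ld_rho == 0.0:
        freqs = np.where(pops[:, None] == 0, p[None, :], p2[None, :])
        dosages = rng.binomial(2, freqs).astype(float)
    else:
        dosages = _ld_block_genotypes(rng, n, m, p, p2, pops, config.ld_block_size, config.ld_rho)

    snps = pd.DataFrame(
        {
            "snp": [f"snp{j}" for j in range(m)],
            "chrom": np.ones(m, dtype=int),
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
            "p_true": p,
        }
    )
    samples = np.array([f"ind{i}" for i in range(n)], dtype=object)
    gm = GenotypeMatrix(dosages, snps, samples)
    if n2 > 0:
        gm.snps.attrs["pop2_freq"] = p2
        gm.population_labels = pops  # type: ignore[attr-defined]
    return gm


def _ld_block_genotypes(rng, n, m, p, p2, pops, block, rho) -> np.ndarray:
    """Haplotypes from a blockwise AR(1) latent Gaussian, thresholded at p."""
    thr1 = stats.norm.isf(p)
    thr2 = stats.norm.isf(p2)
    thr = np.where(pops[:, None] == 0, thr1[None, :], thr2[None, :])
    dos = np.zeros((n, m))
    for _ in range(2):  # two haplotypes
        z = rng.standard_normal((n, m))
        for j in range(1, m):
            if j % block:  # within-block AR(1)
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
        dos += (z > thr).astype(float)
    return dos


def simulate_subtype_effects(config: SimulationConfig, genotypes: GenotypeMatrix) -> TrueEffects:
    """Draw correlated causal effects and rescale to the target heritabilities.

    Per causal SNP ``(beta_1, beta_2)`` come from a bivariate normal with
    correlation ``rho_effects``; each vector is then rescaled so the genetic
    liability variance of standardized genotypes equals ``h2_liab_k`` exactly
    (``sum(beta_k^2) = h2_k``). ``rho_effects = +/-1`` uses the degenerate
    construction ``beta_2 = sign(rho) * beta_1`` before rescaling.
    """
    if abs(config.rho_effects) > 1:
        raise ValueError("|rho_effects| must be <= 1")
    if config.n_causal < 2 and abs(config.rho_effects) != 1:
        raise ValueError("n_causal must be >= 2 when |rho_effects| != 1")
    rng = _stage_rng(config.seed, 1)
    idx = np.sort(rng.choice(genotypes.n_snps, size=config.n_causal, replace=False))
    rho = config.rho_effects
    z1 = rng.standard_normal(config.n_causal)
    if abs(rho) == 1:
        z2 = np.sign(rho) * z1
    else:
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(config.n_causal)
    betas = []
    for z, h2 in ((z1, config.h2_liab_1), (z2, config.h2_liab_2)):
        ss = float(np.sum(z**2))
        betas.append(z * np.sqrt(h2 / ss) if h2 > 0 and ss > 0 else np.zeros_like(z))
    return TrueEffects(causal_indices=idx, beta_1=betas[0], beta_2=betas[1])


def genetic_values(genotypes: GenotypeMatrix, effects: TrueEffects) -> Tuple[np.ndarray, np.ndarray]:
    """True genetic liability contributions, standardizing x by the generative p."""
    idx = effects.causal_indices
    if "p_true" in genotypes.snps.columns:
        p = genotypes.snps["p_true"].to_numpy()[idx]
    else:
        p = genotypes.allele_freq()[idx]
    x = genotypes.dosages[:, idx]
    xs = (np.nan_to_num(x, nan=0.0) - 2 * p) / np.sqrt(2 * p * (1 - p))
    return xs @ effects.beta_1, xs @ effects.beta_2


def assign_liability_phenotypes(
    genotypes: GenotypeMatrix, effects: TrueEffects, config: SimulationConfig
) -> pd.DataFrame:
    """Realize case/control status from the liability-threshold model.

    ``liability_k = g_k + e_k`` with ``e_k ~ N(0, 1 - h2_k)``; an individual
    is a subtype-k case when ``liability_k`` exceeds the threshold
    ``Phi^{-1}(1 - prevalence_k)``. Individuals exceeding both thresholds get
    the subtype with the larger threshold exceedance (subtypes are mutually
    exclusive diagnoses); controls fall below both.
    """
    for k in (config.prevalence_1, config.prevalence_2):
        if not 0 < k < 1:
            raise ValueError("prevalence outside (0,1)")
    rng = _stage_rng(config.seed, 2)
    g1, g2 = genetic_values(genotypes, effects)
    n = genotypes.n_samples
    l1 = g1 + rng.normal(0.0, np.sqrt(1 - config.h2_liab_1), size=n)
    l2 = g2 + rng.normal(0.0, np.sqrt(1 - config.h2_liab_2), size=n)
    t1 = stats.norm.isf(config.prevalence_1)
    t2 = stats.norm.isf(config.prevalence_2)
    exc1, exc2 = l1 - t1, l2 - t2
    is1 = (exc1 > 0) & ((exc2 <= 0) | (exc1 >= exc2))
    is2 = (exc2 > 0) & ~is1
    subtype = np.where(is1, "BD1", np.where(is2, "BD2", "none"))
    status = (is1 | is2).astype(int)
    return pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "status": status,
            "subtype": subtype,
            "site": "pop",
            "liability_1": l1,
            "liability_2": l2,
            "genetic_value_1": g1,
            "genetic_value_2": g2,
        }
    )


def ascertain_cohort(
    population: pd.DataFrame, genotypes: GenotypeMatrix, config: SimulationConfig
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Sample the target case/control counts and assign collection sites.

    Sampling is without replacement within each stratum; sites are assigned
    per ``config.site_mixing`` (columns: BD1 cases, BD2 cases, controls;
    uniform when omitted). Raises if any stratum is smaller than its target.
    """
    rng = _stage_rng(config.seed, 3)
    pools = {
        "BD1": np.flatnonzero((population["subtype"] == "BD1").to_numpy()),
        "BD2": np.flatnonzero((population["subtype"] == "BD2").to_numpy()),
        "none": np.flatnonzero((population["status"] == 0).to_numpy()),
    }
    targets = {
        "BD1": config.target_n_cases_1,
        "BD2": config.target_n_cases_2,
        "none": config.target_n_controls,
    }
    take = []
    sites = []
    sm = config.site_mixing
    if sm is None:
        sm = np.ones((config.n_sites, 3))
    site_names = np.array([f"site{k+1}" for k in range(config.n_sites)], dtype=object)
    for col, key in enumerate(["BD1", "BD2", "none"]):
        want = targets[key]
        pool = pools[key]
        if len(pool) < want:
            raise ValueError(
                f"stratum {key}: population has {len(pool)} individuals, target is {want}"
            )
        chosen = rng.choice(pool, size=want, replace=False)
        take.append(chosen)
        w = sm[:, col] / sm[:, col].sum()
        sites.append(rng.choice(site_names, size=want, p=w))
    idx = np.concatenate(take)
    cohort_geno = genotypes.subset(sample_idx=idx)
    pheno = population.iloc[idx].reset_index(drop=True).copy()
    pheno["site"] = np.concatenate(sites)
    validate_phenotypes(pheno, cohort_geno)
    return cohort_geno, pheno


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[GenotypeMatrix, pd.DataFrame, TrueEffects]:
    """Full generative pipeline: genotypes -> effects -> liabilities -> cohort."""
    pop_geno = simulate_genotypes(config)
    effects = simulate_subtype_effects(config, pop_geno)
    pop_pheno = assign_liability_phenotypes(pop_geno, effects, config)
    cohort_geno, cohort_pheno = ascertain_cohort(pop_pheno, pop_geno, config)
    return cohort_geno, cohort_pheno, effects


# ---------------------------------------------------------------------------
# corruption options: dirty fixtures for the QC stages (defaults elsewhere: none)

def inject_missingness(
    genotypes: GenotypeMatrix,
    rate: float,
    seed: int = 0,
    snp_indices: Optional[np.ndarray] = None,
    sample_mask: Optional[np.ndarray] = None,
) -> GenotypeMatrix:
    """Set a random fraction of calls to missing.

    ``snp_indices`` restricts corruption to given SNPs, ``sample_mask`` to a
    boolean subset of individuals (e.g. cases only, for differential
    missingness fixtures).
    """
    rng = np.random.default_rng(seed)
    d = genotypes.dosages.copy()
    rows = np.arange(genotypes.n_samples) if sample_mask is None else np.flatnonzero(sample_mask)
    cols = np.arange(genotypes.n_snps) if snp_indices is None else np.asarray(snp_indices)
    mask = rng.random((len(rows), len(cols))) < rate
    d[np.ix_(rows, cols)] = np.where(mask, np.nan, d[np.ix_(rows, cols)])
    return GenotypeMatrix(d, genotypes.snps.copy(), genotypes.samples.copy())


def attach_info_scores(
    genotypes: GenotypeMatrix,
    seed: int = 0,
    low_info_indices: Optional[np.ndarray] = None,
    low_info_value: float = 0.2,
) -> GenotypeMatrix:
    """Attach imputation-quality scores (1.0 everywhere except planted lows)."""
    rng = np.random.default_rng(seed)
    info = rng.uniform(0.9, 1.0, size=genotypes.n_snps)
    if low_info_indices is not None:
        info[np.asarray(low_info_indices)] = low_info_value
    meta = genotypes.snps.copy()
    meta["info_score"] = info
    return GenotypeMatrix(genotypes.dosages.copy(), meta, genotypes.samples.copy())
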