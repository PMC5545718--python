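import numpy as np
import pandas as pd
import pytest

from polyhet.simulate import SimulationConfig, simulate_cohort, simulate_genotypes
from polyhet.types import GenotypeMatrix


def small_genotypes(seed=0, n=60, m=40, maf=(0.1, 0.5)) -> GenotypeMatrix:
    cfg = SimulationConfig(
        n_individuals_pop=n, n_snps=m, maf_range=maf, n_causal=min(m, 10),
        target_n_cases_1=1, target_n_cases_2=1, target_n_controls=1, seed=seed,
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Ascertained two-subtype case-control cohort at desk scale."""
    cfg = SimulationConfig(
        n_individuals_pop=12000,
        n_snps=300,
        n_causal=150,
        h2_liab_1=0.5,
        h2_liab_2=0.4,
        rho_effects=0.6,
        prevalence_1=0.02,
        prevalence_2=0.015,
        target_n_cases_1=80,
        target_n_cases_2=60,
        target_n_controls=200,
        n_sites=2,
        seed=1234,
    )
    geno, pheno, effects = simulate_cohort(cfg)
    return cfg, geno, pheno, effects


def make_geno(dosages, chrom=None, pos=None, a1="A", a2="G", ids=None) -> GenotypeMatrix:
    """Hand-built GenotypeMatrix from a raw dosage array."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": np.ones(m, dtype=int) if chrom is None else chrom,
            "pos": np.arange(1, m + 1) * 100 if pos is None else pos,
            "a1": a1,
            "a2": a2,
        }
    )
    samples = np.array([f"i{k}" for k in range(n)], dtype=object) if ids is None else np.asarray(ids, dtype=object)
    return GenotypeMatrix(d, snps, samples)
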