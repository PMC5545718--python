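"""Genetic relationship matrices from allele-frequency-standardized dosages."""

from __future__ import annotations

from typing import List

import numpy as np

from .types import GRM, GenotypeMatrix

__all__ = ["compute_grm", "grm_relatedness_prune"]


def compute_grm(genotypes: GenotypeMatrix, diagonal: str = "standard") -> GRM:
    """Genome-wide similarity A_jk = mean_i z_ij z_ik over shared SNPs.

    ``z = (x - 2p)/sqrt(2p(1-p))`` with ``p`` the sample A1 frequency;
    missing dosages contribute nothing and per-pair SNP counts are recorded.
    ``diagonal="gcta"`` substitutes the GCTA-style diagonal estimator
    ``1 + mean_i (x^2 - (1+2p)x + 2p^2)/(2p(1-p))``; the default uses the
    same standardized product as the off-diagonals.
    """
    p = genotypes.allele_freq()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNPs must be removed before GRM computation")
    d = genotypes.dosages
    denom = np.sqrt(2 * p * (1 - p))
    z = (d - 2 * p[None, :]) / denom[None, :]
    nonmiss = ~np.isnan(d)
    z = np.where(nonmiss, z, 0.0)
    counts = nonmiss.astype(float) @ nonmiss.astype(float).T
    if np.any(counts == 0):
        raise ValueError("a pair of individuals shares no genotyped SNPs")
    values = (z @ z.T) / counts
    if diagonal == "gcta":
        x = np.where(nonmiss, d, 0.0)
        num = x**2 - (1 + 2 * p[None, :]) * x + 2 * p[None, :] ** 2
        num = np.where(nonmiss, num / (2 * p * (1 - p))[None, :], 0.0)
        np.fill_diagonal(values, 1.0 + num.sum(axis=1) / np.diagonal(counts))
    elif diagonal != "standard":
        raise ValueError("diagonal must be 'standard' or 'gcta'")
    values = (values + values.T) / 2.0
    return GRM(values=values, n_snps_used=counts.astype(int), sample_ids=genotypes.samples.copy())


def grm_relatedness_prune(grm: GRM, cutoff: float = 0.05) -> List[str]:
    """Greedy exclusion until no off-diagonal relationship exceeds ``cutoff``.

    Repeatedly removes the individual participating in the most pairs above
    the cutoff (ties: lexicographically larger id removed) and returns the
    retained ids.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    A = grm.values.copy()
    np.fill_diagonal(A, 0.0)
    active = np.ones(grm.n, dtype=bool)
    ids = grm.sample_ids
    while True:
        over = (A > cutoff) & active[:, None] & active[None, :]
        deg = over.sum(axis=1)
        worst = deg.max(initial=0)
        if worst == 0:
            break
        cand = np.flatnonzero(deg == worst)
        # deterministic tie-break on id
        drop = cand[np.argmax(np.array([str(ids[c]) for c in cand], dtype=object))]
        active[drop] = False
    return [str(s) for s in ids[active]]
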