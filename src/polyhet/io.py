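"""Readers and writers for the pipeline's exchange formats.

PLINK bed/bim/fam (SNP-major 2-bit encoding), GCTA-style text GRMs,
tab-separated phenotype tables, summary statistics and YAML pipeline
configuration. Coordinates are 1-based; A1 is the counted/effect allele
throughout; phenotype status is 0=control/1=case internally with the fam
file's 1/2 coding translated at the boundary.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .types import GRM, GenotypeMatrix

__all__ = [
    "write_plink",
    "read_plink",
    "write_pheno",
    "read_pheno",
    "write_grm_text",
    "read_grm_text",
    "write_sumstats",
    "read_sumstats",
    "load_config",
]

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = bytes([0x01])

# 2-bit genotype codes, indexed by A1-dosage: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
_CODE_FOR_DOSAGE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_DOSAGE_FOR_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(genotypes: GenotypeMatrix, prefix: Union[str, Path]) -> None:
    """Write bed/bim/fam with magic bytes 0x6C 0x1B and SNP-major mode."""
    prefix = Path(prefix)
    n, m = genotypes.n_samples, genotypes.n_snps
    d = genotypes.dosages
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing by default
    for dos, code in _CODE_FOR_DOSAGE.items():
        codes[(d.T == dos)] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        packed[:, : len((cols))] |= codes[:, cols] << (2 * k)
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": genotypes.snps["chrom"],
            "snp": genotypes.snps["snp"],
            "cm": 0,
            "pos": genotypes.snps["pos"],
            "a1": genotypes.snps["a1"],
            "a2": genotypes.snps["a2"],
        }
    )
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": genotypes.samples,
            "iid": genotypes.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: Union[str, Path]) -> GenotypeMatrix:
    """Decode a SNP-major PLINK binary fileset into a GenotypeMatrix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        Path(str(prefix) + ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = Path(str(prefix) + ".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise ValueError(
            f"bad bed magic bytes {raw[:2]!r}; expected 0x6C 0x1B"
        )
    if raw[2:3] != _SNP_MAJOR:
        raise ValueError("individual-major bed files are not supported (mode byte != 0x01)")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != m * n_bytes:
        raise ValueError("truncated bed file")
    body = body.reshape(m, n_bytes)
    # unpack 2-bit fields, little-endian within byte
    codes = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _DOSAGE_FOR_CODE[codes[:, :n]].T
    snps = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(dosages, snps, fam["iid"].astype(str).to_numpy(dtype=object))


def write_pheno(phenotypes: pd.DataFrame, path: Union[str, Path]) -> None:
    """Tab-separated phenotype table (sample_id, status, subtype, site, ...)."""
    phenotypes.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pheno(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_grm_text(grm: GRM, prefix: Union[str, Path]) -> None:
    """GCTA-compatible text GRM: lower-triangle rows ``i j n_snps value``.

    Indices are 1-based; values keep full precision. Ids go to
    ``<prefix>.grm.id``.
    """
    prefix = Path(prefix)
    if not np.allclose(grm.values, grm.values.T):
        raise ValueError("GRM must be symmetric")
    n = grm.n
    il, jl = np.tril_indices(n)
    out = pd.DataFrame(
        {
            "i": il + 1,
            "j": jl + 1,
            "n_snps": grm.n_snps_used[il, jl],
            "value": grm.values[il, jl],
        }
    )
    out.to_csv(str(prefix) + ".grm.txt", sep="\t", header=False, index=False, float_format="%.17g")
    ids = pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids})
    ids.to_csv(str(prefix) + ".grm.id", sep="\t", header=False, index=False)


def read_grm_text(prefix: Union[str, Path]) -> GRM:
    prefix = Path(prefix)
    tbl = pd.read_csv(str(prefix) + ".grm.txt", sep="\t", header=None, names=["i", "j", "n", "v"], float_precision="round_trip")
    ids = pd.read_csv(str(prefix) + ".grm.id", sep="\t", header=None, names=["fid", "iid"])
    n = len(ids)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    i = tbl["i"].to_numpy() - 1
    j = tbl["j"].to_numpy() - 1
    values[i, j] = tbl["v"]
    values[j, i] = tbl["v"]
    counts[i, j] = tbl["n"]
    counts[j, i] = tbl["n"]
    return GRM(values=values, n_snps_used=counts, sample_ids=ids["iid"].astype(str).to_numpy(dtype=object))


_SUMSTAT_COLS = ["SNP", "CHR", "BP", "A1", "A2", "FRQ", "BETA", "SE", "P"]


def write_sumstats(stats: pd.DataFrame, path: Union[str, Path]) -> None:
    """Summary statistics as headered TSV (SNP CHR BP A1 A2 FRQ BETA SE P ...)."""
    cols = [c for c in _SUMSTAT_COLS if c in stats.columns]
    extra = [c for c in stats.columns if c not in cols]
    stats[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sumstats(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: Union[str, Path]) -> dict:
    """Load and minimally validate a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
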