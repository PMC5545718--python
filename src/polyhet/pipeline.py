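"""Pipeline orchestration: chain the analysis stages from one config.

Stage order follows the study design: simulate (optional) -> QC -> GRM ->
univariate GREML per subtype (+ liability transform) -> rg permutation
contrast -> GWAS scan (+ inflation factor) -> polygenic scoring. Every
stochastic stage derives its stream from the config seed, a manifest
records inputs, thresholds and per-stage outputs, and a failing stage
aborts with its name while earlier outputs stay on disk.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as phio
from .assoc import genomic_lambda, logistic_assoc_scan
from .contrast import (
    check_site_subtype_balance,
    compare_rg_distributions,
    estimate_rg_distributions,
    generate_split_plans,
)
from .grm import compute_grm, grm_relatedness_prune
from .qc import QCThresholds, snp_qc_filter
from .reml import estimate_liability_h2
from .simulate import SimulationConfig, simulate_cohort
from .types import GenotypeMatrix

__all__ = ["run_pipeline"]


def _validate_config(config: dict) -> dict:
    if "seed" not in config:
        raise ValueError("config must set a seed (all stochastic stages require it)")
    analysis = config.get("analysis", {})
    if analysis.get("reml", False):
        prevs = analysis.get("prevalences")
        if not prevs or len(prevs) < 2:
            raise ValueError("analysis.reml requires analysis.prevalences for the liability transform")
    if "simulate" not in config:
        for key in ("genotype_prefix", "phenotype_file"):
            if key not in config.get("paths", {}):
                raise ValueError(f"paths.{key} required when no simulate block is given")
            if not Path(config["paths"][key] + (".bed" if "prefix" in key else "")).exists():
                raise ValueError(f"paths.{key} does not exist")
    return config


def run_pipeline(config: dict, out_dir: str) -> Path:
    """Execute the configured stages; returns the run directory."""
    config = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config["seed"], "stages": []}
    stage = "start"
    try:
        if "simulate" in config:
            stage = "simulate"
            sim_cfg = SimulationConfig(**{**config["simulate"], "seed": config["seed"]})
            genotypes, phenotypes, effects = simulate_cohort(sim_cfg)
            phio.write_plink(genotypes, out / "cohort")
            phio.write_pheno(phenotypes, out / "cohort.pheno.tsv")
            truth = pd.DataFrame(
                {
                    "snp": genotypes.snps["snp"].to_numpy()[effects.causal_indices],
                    "beta_1": effects.beta_1,
                    "beta_2": effects.beta_2,
                }
            )
            truth.to_csv(out / "cohort.truth.tsv", sep="\t", index=False)
            manifest["stages"].append({"stage": stage, "n": genotypes.n_samples, "m": genotypes.n_snps})
        else:
            stage = "load"
            genotypes = phio.read_plink(config["paths"]["genotype_prefix"])
            phenotypes = phio.read_pheno(config["paths"]["phenotype_file"])
            manifest["stages"].append({"stage": stage, "n": genotypes.n_samples, "m": genotypes.n_snps})

        analysis = config.get("analysis", {})
        if analysis.get("qc", True):
            stage = "qc"
            thr = QCThresholds(**config.get("qc_thresholds", {}))
            genotypes, report = snp_qc_filter(genotypes, phenotypes, thr)
            phenotypes = phenotypes[phenotypes["sample_id"].isin(genotypes.samples)].reset_index(drop=True)
            report.as_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
            manifest["stages"].append(
                {"stage": stage, "thresholds": dataclasses.asdict(thr), "m_after": genotypes.n_snps}
            )

        grm = None
        if analysis.get("grm", True):
            stage = "grm"
            grm = compute_grm(genotypes)
            retained = grm_relatedness_prune(grm, cutoff=analysis.get("grm_cutoff", 0.05))
            if len(retained) < grm.n:
                genotypes = genotypes.subset_samples_by_id(retained)
                phenotypes = phenotypes[phenotypes["sample_id"].isin(retained)].reset_index(drop=True)
                # dropping individuals can leave monomorphic SNPs behind
                p = genotypes.allele_freq()
                genotypes = genotypes.subset(snp_idx=np.flatnonzero((p > 0) & (p < 1)))
                grm = compute_grm(genotypes)
            phio.write_grm_text(grm, out / "cohort")
            manifest["stages"].append({"stage": stage, "n": grm.n})

        if analysis.get("reml", False) and grm is not None:
            stage = "reml"
            prevs = analysis["prevalences"]
            order = {s: i for i, s in enumerate(genotypes.samples)}
            h2 = {}
            for subtype, prev in zip(("BD1", "BD2"), prevs):
                sub = phenotypes[(phenotypes["subtype"].isin([subtype, "none"]))]
                idx = [order[s] for s in sub["sample_id"]]
                A = grm.values[np.ix_(idx, idx)]
                y = (sub["subtype"] == subtype).to_numpy(dtype=float)
                fit, est = estimate_liability_h2(A, y, prev)
                h2[subtype] = {
                    "h2_observed": fit.h2_observed,
                    "h2_liability": est.h2_liability,
                    "se_liability": est.se_liability,
                    "converged": bool(fit.converged),
                }
            (out / "h2.json").write_text(json.dumps(h2, indent=2))
            manifest["stages"].append({"stage": stage, "results": h2})

        if analysis.get("rg_contrast", False) and grm is not None:
            stage = "rg_contrast"
            balance = check_site_subtype_balance(phenotypes)
            plans = generate_split_plans(
                phenotypes,
                n_control_perms=analysis.get("n_control_perms", 10),
                n_case_splits=analysis.get("n_case_splits", 10),
                seed=config["seed"],
            )
            dist = estimate_rg_distributions(genotypes, phenotypes, plans, grm)
            t, p, summary = compare_rg_distributions(dist)
            pd.DataFrame({"rg": dist.rg_subtype, "converged": dist.converged_subtype}).to_csv(
                out / "rg_subtype.tsv", sep="\t", index=False
            )
            pd.DataFrame({"rg": dist.rg_mix, "converged": dist.converged_mix}).to_csv(
                out / "rg_mix.tsv", sep="\t", index=False
            )
            manifest["stages"].append(
                {
                    "stage": stage,
                    "balance_ok": balance.passed,
                    "t": t,
                    "p": p,
                    "summary": summary,
                }
            )

        scan = None
        if analysis.get("gwas", False):
            stage = "gwas"
            y = phenotypes.set_index("sample_id").loc[list(genotypes.samples), "status"].to_numpy(float)
            scan = logistic_assoc_scan(genotypes, y)
            phio.write_sumstats(scan, out / "gwas.tsv")
            lam = genomic_lambda(scan["P"].dropna().to_numpy())
            manifest["stages"].append({"stage": stage, "lambda": lam})

        discovery_path = config.get("paths", {}).get("discovery_stats")
        if analysis.get("signtest", False) and discovery_path and scan is not None:
            stage = "signtest"
            from .assoc import sign_test

            disc = phio.read_sumstats(discovery_path)
            results = sign_test(disc, scan)
            manifest["stages"].append(
                {
                    "stage": stage,
                    "results": {
                        f"{thr:g}": {
                            "n": r.n_index_snps,
                            "concordant": r.n_concordant,
                            "p": r.binomial_p_two_sided,
                        }
                        for thr, r in results.items()
                    },
                }
            )

        if analysis.get("prs", False) and discovery_path:
            stage = "prs"
            from .prs import compute_scores, prs_case_control_test

            disc = phio.read_sumstats(discovery_path)
            profile = compute_scores(genotypes, disc)
            profile.as_frame().to_csv(out / "prs_scores.tsv", sep="\t", index=False)
            tests = prs_case_control_test(profile, phenotypes)
            manifest["stages"].append(
                {
                    "stage": stage,
                    "results": {
                        f"{thr:g}": {
                            "t": r.t_statistic,
                            "p": r.p_value,
                            "delta_r2": r.delta_nagelkerke_r2,
                        }
                        for thr, r in tests.items()
                    },
                }
            )
    except Exception as exc:  # annotate the failing stage, keep earlier outputs
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
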