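"""Permutation contrast of subtype-pair vs mixed-cohort genetic correlations.

The design: the shared control pool is repeatedly split into two even,
non-overlapping halves. Each split yields one *subtype-pair* estimate
(subtype-1 cases + half A vs subtype-2 cases + half B). For every control
split, the pooled cases are additionally re-split at random into two groups
of the same sizes as the subtype groups, yielding *mixed-pair* estimates.
If the subtypes share one genetic architecture the two distributions
coincide; a genuinely lower subtype-pair mean indicates heterogeneity.

A balance gate excludes any subtype dominated by a single collection site
(>75% of its cases) before the contrast is run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .reml import fit_greml_bivariate
from .types import GRM, GenotypeMatrix, RgDistributions, SplitPlan

__all__ = [
    "BalanceReport",
    "check_site_subtype_balance",
    "generate_split_plans",
    "estimate_rg_distributions",
    "compare_rg_distributions",
]


@dataclass
class BalanceReport:
    max_site_share: Dict[str, float]
    site_contribution_ratio: Dict[str, float]
    excluded_subtypes: List[str] = field(default_factory=list)
    excluded_sites: List[str] = field(default_factory=list)
    reasons: Dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return not self.excluded_subtypes and not self.excluded_sites


def check_site_subtype_balance(
    phenotypes: pd.DataFrame,
    subtype_site_share_max: float = 0.75,
    site_imbalance_ratio_max: float = 3.0,
    subtypes: Tuple[str, str] = ("BD1", "BD2"),
) -> BalanceReport:
    """Gatekeeping for the rg contrast: site/subtype composition checks.

    A subtype is excluded when strictly more than ``subtype_site_share_max``
    of its cases come from one site. A site is flagged when its
    contributions to the two compared subtypes are grossly imbalanced
    (ratio above ``site_imbalance_ratio_max``, default 3:1).
    """
    cases = phenotypes[phenotypes["status"] == 1]
    if phenotypes["site"].nunique() < 2:
        raise ValueError("need at least 2 sites")
    report = BalanceReport(max_site_share={}, site_contribution_ratio={})
    for st in subtypes:
        sub = cases[cases["subtype"] == st]
        if len(sub) == 0:
            raise ValueError(f"empty subtype stratum {st!r}")
        share = float(sub["site"].value_counts(normalize=True).iloc[0])
        report.max_site_share[st] = share
        if share > subtype_site_share_max:
            report.excluded_subtypes.append(st)
            report.reasons[st] = (
                f"{share:.0%} of {st} cases from a single site (> {subtype_site_share_max:.0%})"
            )
    counts = (
        cases[cases["subtype"].isin(subtypes)]
        .groupby(["site", "subtype"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(subtypes), fill_value=0)
    )
    tot = counts.sum(axis=0).to_numpy(dtype=float)
    for site, row in counts.iterrows():
        # site's share of each subtype; ratio of the two shares
        shares = row.to_numpy(dtype=float) / np.maximum(tot, 1.0)
        lo, hi = min(shares), max(shares)
        ratio = np.inf if lo == 0 and hi > 0 else (hi / lo if lo > 0 else 1.0)
        report.site_contribution_ratio[str(site)] = float(ratio)
        if ratio > site_imbalance_ratio_max:
            report.excluded_sites.append(str(site))
            report.reasons[str(site)] = (
                f"site contributes {hi:.1%} of one subtype but {lo:.1%} of the other"
            )
    return report


def generate_split_plans(
    phenotypes: pd.DataFrame,
    n_control_perms: int = 100,
    n_case_splits: int = 100,
    seed: int = 0,
    subtype_1: str = "BD1",
    subtype_2: str = "BD2",
) -> List[SplitPlan]:
    """Emit the full permutation design as explicit, reproducible plans.

    Returns ``n_control_perms`` subtype-pair plans (fixed case groups,
    permuted even control halves) followed by
    ``n_control_perms * n_case_splits`` mixed-pair plans (pooled cases
    re-split to the subtype group sizes, re-using each control split).
    """
    controls = phenotypes.loc[phenotypes["status"] == 0, "sample_id"].to_numpy()
    cases_1 = phenotypes.loc[phenotypes["subtype"] == subtype_1, "sample_id"].to_numpy()
    cases_2 = phenotypes.loc[phenotypes["subtype"] == subtype_2, "sample_id"].to_numpy()
    if len(controls) < 2:
        raise ValueError("need at least 2 controls to split")
    if len(cases_1) == 0 or len(cases_2) == 0:
        raise ValueError("both subtype case groups must be non-empty")
    pooled = np.concatenate([cases_1, cases_2])
    n1, n2 = len(cases_1), len(cases_2)
    if len(pooled) < n1 + n2:
        raise ValueError("case pool smaller than required split sizes")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10,)))
    half = len(controls) // 2
    plans: List[SplitPlan] = []
    mixed: List[SplitPlan] = []
    for i in range(n_control_perms):
        perm = rng.permutation(controls)
        ctrl_a, ctrl_b = perm[: len(controls) - half], perm[len(controls) - half :]
        plans.append(
            SplitPlan(
                permutation_index=i,
                control_group_A=ctrl_a,
                control_group_B=ctrl_b,
                case_group_1=cases_1.copy(),
                case_group_2=cases_2.copy(),
                kind="subtype_pair",
                seed_state=seed,
            )
        )
        for j in range(n_case_splits):
            cperm = rng.permutation(pooled)
            mixed.append(
                SplitPlan(
                    permutation_index=i * n_case_splits + j,
                    control_group_A=ctrl_a,
                    control_group_B=ctrl_b,
                    case_group_1=cperm[:n1],
                    case_group_2=cperm[n1 : n1 + n2],
                    kind="mixed_pair",
                    seed_state=seed,
                )
            )
    return plans + mixed


def estimate_rg_distributions(
    genotypes: Optional[GenotypeMatrix],
    phenotypes: pd.DataFrame,
    plans: List[SplitPlan],
    grm: GRM,
) -> RgDistributions:
    """Run a bivariate GREML per plan and collect the rg estimates.

    Trait 1 is case_group_1 (1) vs control_group_A (0); trait 2 likewise
    with group 2 / half B. Non-converged fits are flagged, never dropped.
    The ``genotypes`` argument is accepted for interface symmetry; the fits
    require only the GRM.
    """
    grm_ids = set(grm.sample_ids)
    rg_sub, rg_mix, conv_sub, conv_mix = [], [], [], []
    for plan in plans:
        plan.validate()
        members = np.concatenate(
            [plan.case_group_1, plan.control_group_A, plan.case_group_2, plan.control_group_B]
        )
        if not set(members) <= grm_ids:
            raise ValueError("GRM does not cover all plan individuals")
        y1 = pd.Series(
            np.r_[np.ones(len(plan.case_group_1)), np.zeros(len(plan.control_group_A))],
            index=np.r_[plan.case_group_1, plan.control_group_A],
        )
        y2 = pd.Series(
            np.r_[np.ones(len(plan.case_group_2)), np.zeros(len(plan.control_group_B))],
            index=np.r_[plan.case_group_2, plan.control_group_B],
        )
        comps, est = fit_greml_bivariate(grm, y1, y2)
        if plan.kind == "subtype_pair":
            rg_sub.append(est.rg)
            conv_sub.append(comps.converged)
        else:
            rg_mix.append(est.rg)
            conv_mix.append(comps.converged)
    return RgDistributions(
        rg_subtype=np.array(rg_sub),
        rg_mix=np.array(rg_mix),
        converged_subtype=np.array(conv_sub, dtype=bool),
        converged_mix=np.array(conv_mix, dtype=bool),
    )


def compare_rg_distributions(dist: RgDistributions) -> Tuple[float, float, dict]:
    """Welch two-sample t-test between the converged rg estimate vectors.

    Returns (t, two-sided p, summary) where the summary holds mean, sd and
    range per arm plus convergence counts.
    """
    a = dist.rg_subtype[dist.converged_subtype]
    b = dist.rg_mix[dist.converged_mix]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 converged estimates in each arm")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), dist.summary()
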