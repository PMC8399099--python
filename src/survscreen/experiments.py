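"""Predefined simulation studies exercising the whole pipeline.

These are the package's standard reproducibility experiments: each function
generates its own synthetic cohorts, runs the screen, and returns summary
numbers.  They are deliberately deterministic given a seed so that reported
results can be recomputed exactly.

Problem sizes (400 patients, a few hundred genes, tens to hundreds of
replicates) are chosen so every study completes in minutes on one CPU while
keeping Monte-Carlo error well inside the margins being asserted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cutpoints import scan_all
from .screen import screen_cohort
from .selection import CandidateCriteria, apply_gates, consensus, hr_concordance
from .simulate import GeneEffectSpec, SimConfig, simulate_dataset, simulate_null_screen
from .stats import cox_fit

__all__ = [
    "null_screen_inflation",
    "cut_recovery_study",
    "consensus_study",
    "CONSENSUS_EFFECTS",
]

#: covariate effects switched off (correctly specified marginal gene models)
_NO_COVARIATE_EFFECTS = {
    name: 0.0
    for name in (
        "male", "age_gt_65", "t34", "n_positive", "m1",
        "late_stage", "margin_positive", "tobacco_high",
    )
}

#: planted effects of the end-to-end consensus study.  Harmful effects sit at
#: or above the median because a median-cut validation screen dilutes a step
#: that lies below it (the low group absorbs part of the high-risk stratum,
#: dragging the marginal hazard ratio inside the effect gate); effect sizes
#: are strong enough to survive the marginal attenuation caused by the other
#: planted genes (omitted-covariate non-collapsibility).
CONSENSUS_EFFECTS = (
    GeneEffectSpec("threshold", q=0.55, hr=6.0),
    GeneEffectSpec("threshold", q=0.45, hr=0.25),
    GeneEffectSpec("threshold", q=0.50, hr=0.30),
)


def null_screen_inflation(
    n_patients: int = 400, n_genes: int = 500, seed: int = 11
) -> dict:
    """Fraction of null genes reaching raw p < 0.05 under both strategies.

    The optimal-cut minimum-p screen is anti-conservative by construction;
    the fixed median cut is a single pre-specified test and stays nominal.
    """
    dataset = simulate_null_screen(n_patients=n_patients, n_genes=n_genes, seed=seed)
    optimal, _ = scan_all(dataset, mode="optimal")
    median, _ = scan_all(dataset, mode="median")
    return {
        "n_genes": int(len(optimal)),
        "optimal_sig_fraction": float((optimal["p_raw"] < 0.05).mean()),
        "median_sig_fraction": float((median["p_raw"] < 0.05).mean()),
    }


def cut_recovery_study(
    n_replicates: int = 200,
    n_patients: int = 400,
    q: float = 0.4,
    hr: float = 2.5,
    seed: int = 0,
) -> dict:
    """Parameter recovery for a single planted threshold gene.

    Per replicate: (a) the optimal-cut scan's selected rank is compared with
    the true cut quantile; (b) a Cox model fitted at the *true* split checks
    Wald CI coverage of the planted hazard ratio.  Uses exponential times
    with ~25-30% censoring and no clinical covariate effects so the marginal
    gene model is correctly specified.
    """
    errors, covered = [], 0
    for r in range(n_replicates):
        cfg = SimConfig(
            n_patients=n_patients,
            n_genes=1,
            effects=(GeneEffectSpec("threshold", q=q, hr=hr),),
            baseline_rate=4e-4,
            dropout_rate=2e-4,
            covariate_log_hazards=dict(_NO_COVARIATE_EFFECTS),
            seed=seed + r,
        )
        dataset, truth = simulate_dataset(cfg)
        table, _ = scan_all(dataset, mode="optimal")
        errors.append(abs(table["rank"].iloc[0] / n_patients - q))
        groups = truth.true_groups.iloc[0].to_numpy(float)
        res = cox_fit(pd.DataFrame({"gene": groups}), dataset.times, dataset.events)
        lo, hi = res.ci("gene")
        covered += int(lo <= hr <= hi)
    return {
        "n_replicates": n_replicates,
        "median_abs_error": float(np.median(errors)),
        "ci_coverage": covered / n_replicates,
    }


def _two_cohort_run(seed_discovery: int, seed_validation: int, n_genes: int):
    common = dict(
        n_patients=400,
        n_genes=n_genes,
        effects=CONSENSUS_EFFECTS,
        baseline_rate=4e-4,
        dropout_rate=2e-4,
    )
    discovery, _ = simulate_dataset(SimConfig(seed=seed_discovery, **common))
    validation, _ = simulate_dataset(SimConfig(seed=seed_validation, **common))
    disc = screen_cohort(discovery, mode="optimal", cox_stage="bonferroni", stage_threshold=0.05)
    candidates = apply_gates(disc.table, CandidateCriteria(), stage="bonferroni")
    val = screen_cohort(
        validation,
        mode="median",
        cox_stage="raw",
        stage_threshold=1.1,  # always fit Cox for the shortlisted genes
        genes=list(candidates["gene"]),
    )
    return consensus(candidates, val.table), candidates, val.table


def consensus_study(n_runs: int = 50, n_genes: int = 303, seed: int = 0) -> dict:
    """End-to-end two-cohort recovery of three planted genes among nulls.

    Each run simulates an independent discovery and validation cohort with
    the same generative truth, screens the discovery cohort with the
    optimal-cut strategy + Bonferroni gate, validates at median cutpoints
    with the FDR gate, and intersects.  Reports how often all three planted
    genes are recovered with the correct direction, the per-run false
    positives, and the between-cohort concordance of the candidate hazard
    ratios.
    """
    planted = {"G00001": "harmful", "G00002": "protective", "G00003": "protective"}
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_runs) % (2**31)
    all_three = 0
    false_positives = []
    direction_errors = 0
    hr_pairs = []
    for r in range(n_runs):
        cons, candidates, val_table = _two_cohort_run(
            int(seeds[2 * r]), int(seeds[2 * r + 1]), n_genes
        )
        hits = cons.loc[cons["validated"]]
        recovered = set(hits["gene"]) & set(planted)
        false_positives.append(int(len(set(hits["gene"]) - set(planted))))
        if recovered == set(planted):
            all_three += 1
        for _, row in hits.iterrows():
            if row["gene"] in planted and row["discovery_direction"] != planted[row["gene"]]:
                direction_errors += 1
        disc_hr = candidates.set_index("gene")["uni_hr"]
        val_hr = val_table.set_index("gene")["uni_hr"]
        for gene in hits["gene"]:
            hr_pairs.append((float(disc_hr[gene]), float(val_hr[gene])))
    out = {
        "n_runs": n_runs,
        "all_recovered_fraction": all_three / n_runs,
        "direction_errors": direction_errors,
        "max_false_positives": int(max(false_positives)),
        "mean_false_positives": float(np.mean(false_positives)),
    }
    if len(hr_pairs) >= 3:
        x, y = zip(*hr_pairs)
        out["hr_concordance_r"] = hr_concordance(x, y)
    return out
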