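"""Candidate gates, strategy comparison, and two-cohort consensus.

A gene becomes a candidate when its stage-adjusted Kaplan-Meier p value
(FDR or Bonferroni) clears the threshold AND both Cox hazard ratios — the
single-covariate fit and the confounder-adjusted joint fit — sit on the same
side of the effect-size gate (both >= ``hr_high`` or both <= ``hr_low``).
A consensus biomarker additionally passes the validation cohort's
median-cutpoint screen with the same effect direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import AnalysisDataset
from .adjust import adjust_pvalues
from .cutpoints import scan_all

__all__ = [
    "CandidateCriteria",
    "apply_gates",
    "consensus",
    "compare_strategies",
    "hr_concordance",
    "volcano_data",
]


@dataclass(frozen=True)
class CandidateCriteria:
    fdr_threshold: float = 0.05
    bonferroni_threshold: float = 0.05
    hr_low: float = 0.6
    hr_high: float = 1.8

    def __post_init__(self):
        if not (0 < self.hr_low < 1 < self.hr_high):
            raise ValueError("need 0 < hr_low < 1 < hr_high")


def _direction(uni_hr, multi_hr, criteria: CandidateCriteria) -> str | None:
    """'harmful'/'protective' when both models clear the gate on one side."""
    if np.isnan(uni_hr) or np.isnan(multi_hr):
        return None
    if uni_hr >= criteria.hr_high and multi_hr >= criteria.hr_high:
        return "harmful"
    if uni_hr <= criteria.hr_low and multi_hr <= criteria.hr_low:
        return "protective"
    return None


def apply_gates(
    results: pd.DataFrame,
    criteria: CandidateCriteria = CandidateCriteria(),
    stage: str = "bonferroni",
) -> pd.DataFrame:
    """Filter a per-gene result table down to the candidates.

    ``stage`` picks which adjusted p enters the significance gate ('fdr' for
    the initial screen, 'bonferroni' for final candidate selection).  The
    returned table gains a ``direction`` column.
    """
    if stage not in ("fdr", "bonferroni"):
        raise ValueError(f"unknown stage {stage!r}")
    pcol = {"fdr": "fdr_p", "bonferroni": "bonferroni_p"}[stage]
    threshold = {"fdr": criteria.fdr_threshold, "bonferroni": criteria.bonferroni_threshold}[stage]
    out = results.copy()
    out["direction"] = [
        _direction(u, m, criteria)
        for u, m in zip(out["uni_hr"].fillna(np.nan), out["multi_hr"].fillna(np.nan))
    ]
    keep = (out[pcol] < threshold) & out["direction"].notna()
    return out[keep].reset_index(drop=True)


def consensus(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    criteria: CandidateCriteria = CandidateCriteria(),
) -> pd.DataFrame:
    """Cross the discovery candidates against the validation screen.

    Validation (run in median-cutpoint mode) must show FDR p below the
    threshold, both hazard ratios clearing the effect gate, and the same
    direction as discovery.  Genes absent from the validation cohort are
    recorded as not validated, never as errors.
    """
    val = validation.set_index("gene") if "gene" in validation.columns else validation
    rows = []
    for _, row in discovery.iterrows():
        gene = row["gene"]
        entry = {
            "gene": gene,
            "discovery_direction": row["direction"],
            "discovery_bonferroni_p": row.get("bonferroni_p", np.nan),
            "validated": False,
            "reason": "",
        }
        if gene not in val.index:
            entry["reason"] = "absent from validation cohort"
        else:
            v = val.loc[gene]
            v_dir = _direction(v["uni_hr"], v["multi_hr"], criteria)
            if not (v["fdr_p"] < criteria.fdr_threshold):
                entry["reason"] = "validation FDR p above threshold"
            elif v_dir is None:
                entry["reason"] = "validation hazard ratios inside the effect gate"
            elif v_dir != row["direction"]:
                entry["reason"] = "effect direction flipped between cohorts"
            else:
                entry["validated"] = True
                entry["validation_fdr_p"] = float(v["fdr_p"])
                entry["validation_uni_hr"] = float(v["uni_hr"])
                entry["validation_multi_hr"] = float(v["multi_hr"])
        rows.append(entry)
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "discovery_direction",
            "discovery_bonferroni_p",
            "validated",
            "reason",
            "validation_fdr_p",
            "validation_uni_hr",
            "validation_multi_hr",
        ],
    )


def compare_strategies(
    dataset: AnalysisDataset,
    lo_frac: float = 0.30,
    hi_frac: float = 0.70,
    sig_level: float = 0.05,
) -> dict:
    """Tabulate significant-gene counts under the sliding-window optimal cut
    versus the fixed median cut (raw p < 0.05 and FDR p < 0.05)."""
    counts = {}
    for mode in ("optimal", "median"):
        table, _ = scan_all(
            dataset, lo_frac=lo_frac, hi_frac=hi_frac, sig_level=sig_level, mode=mode
        )
        if table.empty:
            counts[mode] = {"raw": 0, "fdr": 0, "n_genes": 0}
            continue
        adj = adjust_pvalues(table["p_raw"].to_numpy())
        counts[mode] = {
            "raw": int((adj.raw < sig_level).sum()),
            "fdr": int((adj.fdr < sig_level).sum()),
            "n_genes": int(len(table)),
        }
    return counts


def hr_concordance(hr_discovery, hr_validation, log_scale: bool = False) -> float:
    """Pearson correlation of per-gene hazard ratios across two cohorts.

    Computed on the HR scale by default (matching how concordance is usually
    plotted); ``log_scale`` switches to log-HR, which is symmetric in the
    harmful/protective directions.
    """
    x = np.asarray(hr_discovery, float)
    y = np.asarray(hr_validation, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired hazard ratios")
    if log_scale:
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in hazard ratios")
    return float(sps.pearsonr(x, y).statistic)


def volcano_data(
    results: pd.DataFrame, p_col: str = "fdr_p", hr_col: str = "uni_hr"
) -> pd.DataFrame:
    """Per-gene (log10 adjusted p, HR, direction) table for volcano plotting."""
    if results.empty:
        return pd.DataFrame(columns=["gene", "log10_p", "hr", "direction"])
    out = pd.DataFrame(
        {
            "gene": results["gene"],
            "log10_p": np.log10(results[p_col].to_numpy(float)),
            "hr": results[hr_col].to_numpy(float),
        }
    )
    out["direction"] = np.where(out["hr"] > 1.0, "harmful", "protective")
    return out
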