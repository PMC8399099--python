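"""End-to-end per-cohort screen: scan -> adjust -> Cox models -> gene table.

This is the functional core behind both the CLI and the sklearn-style
estimators.  For each gene the screen records the selected cutpoint, the raw
minimum log-rank p, its FDR and Bonferroni adjustments (family = all genes
that completed scanning), and — for genes passing the chosen stage gate —
the univariate and confounder-adjusted Cox hazard ratios of the
high-expression group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjust import adjust_pvalues
from .cohort import AnalysisDataset
from .cutpoints import scan_all
from .exceptions import GeneAnalysisError
from .stats import cox_fit, multivariate_fit

__all__ = ["ScreenResult", "screen_cohort", "gene_indicator"]

RESULT_COLUMNS = [
    "gene",
    "n_used",
    "rank",
    "n_low",
    "n_high",
    "cutoff_value",
    "p_raw",
    "used_fallback",
    "n_valid_positions",
    "fdr_p",
    "bonferroni_p",
    "uni_hr",
    "uni_ci_low",
    "uni_ci_high",
    "uni_p",
    "multi_hr",
    "multi_ci_low",
    "multi_ci_high",
    "multi_p",
]


@dataclass
class ScreenResult:
    table: pd.DataFrame
    failures: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def error_proportions(self) -> dict[str, float]:
        """Share of each failure category among failed genes."""
        if self.failures.empty:
            return {}
        counts = self.failures["category"].value_counts()
        return (counts / counts.sum()).to_dict()


def gene_indicator(dataset: AnalysisDataset, gene: str, cutoff_value: float) -> pd.Series:
    """High-expression indicator (expression > cutoff); NaN where null."""
    vals, null = dataset.gene_values(gene)
    ind = (vals > cutoff_value).astype(float)
    ind[null] = np.nan
    return pd.Series(ind, index=dataset.patients, name=gene)


def screen_cohort(
    dataset: AnalysisDataset,
    mode: str = "optimal",
    lo_frac: float = 0.30,
    hi_frac: float = 0.70,
    sig_level: float = 0.05,
    cox_stage: str = "fdr",
    stage_threshold: float = 0.05,
    bonferroni_m: int | None = None,
    genes=None,
    fit_cox: bool = True,
    tie_method: str = "efron",
) -> ScreenResult:
    """Screen one cohort gene by gene.

    ``cox_stage`` picks which adjusted p ('fdr' or 'bonferroni', or 'raw')
    must fall below ``stage_threshold`` before the (comparatively expensive)
    Cox models are fitted for a gene; genes failing the gate keep NaN hazard
    ratios.  ``bonferroni_m`` overrides the Bonferroni family size (default:
    number of genes that completed scanning).
    """
    table, failures = scan_all(
        dataset, lo_frac=lo_frac, hi_frac=hi_frac, sig_level=sig_level, mode=mode, genes=genes
    )
    config = {
        "mode": mode,
        "lo_frac": lo_frac,
        "hi_frac": hi_frac,
        "sig_level": sig_level,
        "cox_stage": cox_stage,
        "stage_threshold": stage_threshold,
        "tie_method": tie_method,
    }
    if table.empty:
        return ScreenResult(pd.DataFrame(columns=RESULT_COLUMNS), failures, config)

    adj = adjust_pvalues(table["p_raw"].to_numpy(), m=bonferroni_m)
    table = table.assign(fdr_p=adj.fdr, bonferroni_p=adj.bonferroni)
    config["bonferroni_m"] = adj.m

    for col in ("uni_hr", "uni_ci_low", "uni_ci_high", "uni_p",
                "multi_hr", "multi_ci_low", "multi_ci_high", "multi_p"):
        table[col] = np.nan

    if fit_cox:
        stage_col = {"raw": "p_raw", "fdr": "fdr_p", "bonferroni": "bonferroni_p"}[cox_stage]
        fit_rows = table.index[table[stage_col] < stage_threshold]
        drop = []
        for i in fit_rows:
            gene = table.at[i, "gene"]
            groups = gene_indicator(dataset, gene, table.at[i, "cutoff_value"])
            keep = groups.notna()
            t = dataset.clinical.loc[keep, "time"].to_numpy(float)
            e = dataset.clinical.loc[keep, "event"].to_numpy(int)
            try:
                uni = cox_fit(groups[keep].to_frame("gene"), t, e, tie_method=tie_method)
                multi = multivariate_fit(dataset, groups, tie_method=tie_method)
            except GeneAnalysisError as exc:
                failures = pd.concat(
                    [
                        failures,
                        pd.DataFrame(
                            [{"gene": gene, "category": exc.category, "reason": str(exc)}]
                        ),
                    ],
                    ignore_index=True,
                )
                drop.append(i)
                continue
            u = uni.summary.loc["gene"]
            m = multi.summary.loc["gene"]
            table.loc[i, ["uni_hr", "uni_ci_low", "uni_ci_high", "uni_p"]] = [
                u["hr"], u["ci_low"], u["ci_high"], u["p"]
            ]
            table.loc[i, ["multi_hr", "multi_ci_low", "multi_ci_high", "multi_p"]] = [
                m["hr"], m["ci_low"], m["ci_high"], m["p"]
            ]
        if drop:
            table = table.drop(index=drop).reset_index(drop=True)

    return ScreenResult(table[RESULT_COLUMNS], failures, config)
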