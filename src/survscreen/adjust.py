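"""Gene-wise multiple-testing adjustment: Benjamini-Hochberg FDR and Bonferroni.

The family is one p value per gene — each gene's optimal (minimum) log-rank
p — across all genes that completed scanning.  The within-gene multiplicity
of the ~166 serial cuts is deliberately NOT corrected separately; the
screen-level FDR/Bonferroni gates (and external-cohort validation) are what
tame the minimum-p selection bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["AdjustedPValues", "bh_adjust", "bonferroni_adjust", "adjust_pvalues"]


def _validate(raw) -> np.ndarray:
    p = np.asarray(raw, float)
    if p.size and (np.isnan(p).any() or (p <= 0).any() or (p > 1).any()):
        raise ValueError("p values must lie in (0, 1]")
    return p


@dataclass(frozen=True)
class AdjustedPValues:
    raw: np.ndarray
    fdr: np.ndarray
    bonferroni: np.ndarray
    m: int


def bh_adjust(raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = _validate(raw)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(raw, m: int | None = None) -> np.ndarray:
    """min(1, p*m) elementwise; ``m`` defaults to the vector length."""
    p = _validate(raw)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than the number of tests {p.size}")
    return np.minimum(1.0, p * m)


def adjust_pvalues(raw, m: int | None = None) -> AdjustedPValues:
    p = _validate(raw)
    return AdjustedPValues(p, bh_adjust(p), bonferroni_adjust(p, m), int(m or p.size))
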