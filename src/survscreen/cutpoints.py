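"""Sliding-window optimal-cutpoint engine.

For one gene, patients are ordered by expression and a serial cut slides
across the ranks lying between the ``lo_frac`` and ``hi_frac`` percentiles of
the cohort (default 30%-70%, which avoids tiny groups).  Every cut splits the
cohort into a low-expression group (ranks 1..k) and a high-expression group
(ranks k+1..N) and is scored with a two-group log-rank test.  The optimal
cutpoint is the cut with the minimum p value; when no cut reaches the
significance level the gene falls back to its median expression cutpoint.

Cuts that would split tied expression values are skipped (the rank split
would not correspond to any expression threshold), as are cuts leaving one
group without events; a gene where every position is skipped is a
categorized failure, not a crash.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import ceil, floor

import numpy as np
import pandas as pd

from .cohort import AnalysisDataset
from .exceptions import EmptyGridError, GeneAnalysisError
from .stats import _logrank_grid

__all__ = [
    "CutGrid",
    "CutoffScan",
    "OptimalCut",
    "candidate_positions",
    "rank_patients",
    "scan_gene",
    "select_optimal",
    "cut_at_median",
    "scan_all",
]

STATUS_VALID = "valid"
STATUS_TIE = "skipped_tie"
STATUS_DEGENERATE = "skipped_degenerate"


@dataclass(frozen=True)
class CutGrid:
    """Candidate cut ranks: floor(lo*N)+1 .. ceil(hi*N), all 1 <= k < N."""

    n_patients: int
    lo_frac: float
    hi_frac: float
    positions: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class CutoffScan:
    """Per-position log-rank profile of one gene's serial cut."""

    gene: str
    order: np.ndarray  # permutation sorting patients by ascending expression
    positions: np.ndarray
    status: np.ndarray  # one of the STATUS_* strings per position
    p_values: np.ndarray  # NaN where skipped
    sorted_values: np.ndarray
    sorted_times: np.ndarray
    sorted_events: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.status == STATUS_VALID

    @property
    def failed(self) -> bool:
        return not bool(self.valid.any())

    def profile_frame(self) -> pd.DataFrame:
        """Exportable per-position table (for cumulative-p plotting)."""
        n = len(self.sorted_values)
        return pd.DataFrame(
            {
                "gene": self.gene,
                "rank": self.positions,
                "n_low": self.positions,
                "n_high": n - self.positions,
                "p": self.p_values,
                "status": self.status,
            }
        )


@dataclass(frozen=True)
class OptimalCut:
    """Selected cutpoint: the low group holds the ``n_low`` lowest values."""

    gene: str
    rank_k: int
    n_low: int
    n_high: int
    cutoff_value: float
    p_min: float
    used_fallback: bool
    n_valid_positions: int


def _exact_fraction(x: float) -> Fraction:
    """Exact rational value of a user-supplied fraction.

    ``Fraction(str(x))`` recovers the decimal the caller typed (0.3 means
    3/10, not the nearest binary double), so grid boundaries land on the
    intended ranks even when lo*N is an integer.
    """
    try:
        return Fraction(str(float(x)))
    except ValueError:  # pragma: no cover - inf/nan rejected upstream
        return Fraction(x)


def candidate_positions(
    n_patients: int, lo_frac: float = 0.30, hi_frac: float = 0.70
) -> CutGrid:
    """Candidate cut ranks between the lo and hi percentiles of the cohort.

    The grid is {k : lo*N < k <= ceil(hi*N)} intersected with 1 <= k < N,
    i.e. ranks floor(lo*N)+1 through ceil(hi*N) inclusive.
    """
    if n_patients < 10:
        raise ValueError("need at least 10 patients to place a cut grid")
    lo, hi = _exact_fraction(lo_frac), _exact_fraction(hi_frac)
    if not (0 < lo < hi < 1):
        raise ValueError("fractions must satisfy 0 < lo < hi < 1")
    first = floor(lo * n_patients) + 1
    last = ceil(hi * n_patients)
    first = max(first, 1)
    last = min(last, n_patients - 1)
    if last < first:
        raise EmptyGridError(
            f"no cut position between fractions {lo_frac} and {hi_frac} of {n_patients}"
        )
    return CutGrid(n_patients, float(lo_frac), float(hi_frac), np.arange(first, last + 1))


def rank_patients(values, patient_ids=None) -> np.ndarray:
    """Stable ascending expression order; ties broken by patient id."""
    values = np.asarray(values, float)
    if patient_ids is None:
        return np.argsort(values, kind="stable")
    ids = np.asarray(patient_ids)
    return np.lexsort((ids, values))


def scan_gene(
    values,
    times,
    events,
    grid: CutGrid | None = None,
    patient_ids=None,
    gene: str = "gene",
) -> CutoffScan:
    """Serial-cut log-rank scan of one gene across the grid positions."""
    values = np.asarray(values, float)
    if np.isnan(values).any():
        raise ValueError("missing expression values must be handled upstream")
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if not (values.size == t.size == e.size):
        raise ValueError("expression and survival vectors must align")
    if grid is None:
        grid = candidate_positions(values.size)
    order = rank_patients(values, patient_ids)
    sv, st, se = values[order], t[order], e[order]
    ks = grid.positions
    chi, p, var, low_ev, high_ev = _logrank_grid(st, se, ks)
    tie = sv[ks - 1] == sv[ks]  # cut would split equal expression values
    degenerate = (low_ev == 0) | (high_ev == 0) | (var <= 0) | ~np.isfinite(p)
    status = np.where(tie, STATUS_TIE, np.where(degenerate, STATUS_DEGENERATE, STATUS_VALID))
    p_out = np.where(status == STATUS_VALID, p, np.nan)
    return CutoffScan(gene, order, ks.copy(), status, p_out, sv, st, se)


def _value_split_logrank(sorted_values, sorted_times, sorted_events, cutoff_value):
    """Log-rank p for the split low = {expression <= cutoff_value}."""
    n_low = int(np.searchsorted(sorted_values, cutoff_value, side="right"))
    n = sorted_values.size
    if n_low == 0 or n_low == n:
        raise GeneAnalysisError("one-group-logrank", "median split leaves one group empty")
    chi, p, var, low_ev, high_ev = _logrank_grid(sorted_times, sorted_events, np.array([n_low]))
    if low_ev[0] == 0 or high_ev[0] == 0 or var[0] <= 0 or not np.isfinite(p[0]):
        raise GeneAnalysisError("one-group-logrank", "median split has an event-free group")
    return n_low, float(p[0])


def select_optimal(scan: CutoffScan, sig_level: float = 0.05) -> OptimalCut:
    """Pick the minimum-p cut; fall back to the median cutpoint otherwise.

    Fallback: the cutoff value is the expression at rank floor(N/2) and the
    low group is every patient at or below that value, so tied boundaries
    never produce an ambiguous split.  A fallback that still leaves one group
    empty or event-free excludes the gene (categorized failure).
    """
    n = scan.sorted_values.size
    valid = scan.valid
    n_valid = int(valid.sum())
    if n_valid and np.nanmin(scan.p_values[valid]) < sig_level:
        idx = int(np.nanargmin(np.where(valid, scan.p_values, np.inf)))
        k = int(scan.positions[idx])
        return OptimalCut(
            gene=scan.gene,
            rank_k=k,
            n_low=k,
            n_high=n - k,
            cutoff_value=float(scan.sorted_values[k - 1]),
            p_min=float(scan.p_values[idx]),
            used_fallback=False,
            n_valid_positions=n_valid,
        )
    median_rank = n // 2
    if median_rank < 1:
        raise GeneAnalysisError("unknown", "cohort too small for a median cut")
    cutoff_value = float(scan.sorted_values[median_rank - 1])
    n_low, p_med = _value_split_logrank(
        scan.sorted_values, scan.sorted_times, scan.sorted_events, cutoff_value
    )
    return OptimalCut(
        gene=scan.gene,
        rank_k=n_low,
        n_low=n_low,
        n_high=n - n_low,
        cutoff_value=cutoff_value,
        p_min=p_med,
        used_fallback=True,
        n_valid_positions=n_valid,
    )


def cut_at_median(values, times, events, patient_ids=None, gene: str = "gene") -> OptimalCut:
    """Fixed median-expression cutpoint (the non-adaptive strategy)."""
    values = np.asarray(values, float)
    if np.isnan(values).any():
        raise ValueError("missing expression values must be handled upstream")
    order = rank_patients(values, patient_ids)
    sv = values[order]
    st = np.asarray(times, float)[order]
    se = np.asarray(events, int)[order]
    n = sv.size
    median_rank = n // 2
    if median_rank < 1:
        raise GeneAnalysisError("unknown", "cohort too small for a median cut")
    cutoff_value = float(sv[median_rank - 1])
    n_low, p_med = _value_split_logrank(sv, st, se, cutoff_value)
    return OptimalCut(gene, n_low, n_low, n - n_low, cutoff_value, p_med, True, 0)


def scan_all(
    dataset: AnalysisDataset,
    lo_frac: float = 0.30,
    hi_frac: float = 0.70,
    sig_level: float = 0.05,
    mode: str = "optimal",
    genes=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every gene; failures are categorized, never fatal.

    Patients with a null value for a gene are excluded from that gene's scan
    and the cut grid is recomputed on the remaining N.  Returns the per-gene
    optimal-cut table and the failure log (gene, category, reason).
    """
    if mode not in ("optimal", "median"):
        raise ValueError(f"unknown mode {mode!r}")
    gene_list = list(genes) if genes is not None else list(dataset.genes)
    times, events = dataset.times, dataset.events
    ids = dataset.patients.to_numpy()
    rows, failures = [], []
    for gene in gene_list:
        vals, null = dataset.gene_values(gene)
        keep = ~null
        n_used = int(keep.sum())
        try:
            if n_used < 10:
                raise GeneAnalysisError(
                    "unknown", f"only {n_used} patients with usable expression"
                )
            v, t, e = vals[keep], times[keep], events[keep]
            pid = ids[keep]
            if mode == "optimal":
                try:
                    grid = candidate_positions(n_used, lo_frac, hi_frac)
                except EmptyGridError as exc:
                    raise GeneAnalysisError("unknown", str(exc)) from exc
                scan = scan_gene(v, t, e, grid=grid, patient_ids=pid, gene=gene)
                cut = select_optimal(scan, sig_level=sig_level)
                n_valid = cut.n_valid_positions
            else:
                cut = cut_at_median(v, t, e, patient_ids=pid, gene=gene)
                n_valid = 1
            rows.append(
                {
                    "gene": gene,
                    "n_used": n_used,
                    "rank": cut.rank_k,
                    "n_low": cut.n_low,
                    "n_high": cut.n_high,
                    "cutoff_value": cut.cutoff_value,
                    "p_raw": cut.p_min,
                    "used_fallback": cut.used_fallback,
                    "n_valid_positions": n_valid,
                }
            )
        except GeneAnalysisError as exc:
            failures.append({"gene": gene, "category": exc.category, "reason": str(exc)})
    table = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_used",
            "rank",
            "n_low",
            "n_high",
            "cutoff_value",
            "p_raw",
            "used_fallback",
            "n_valid_positions",
        ],
    )
    fail_table = pd.DataFrame(failures, columns=["gene", "category", "reason"])
    return table, fail_table
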