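"""Scikit-learn style estimator facades over the screening core.

``CutpointDichotomizer`` is a transformer: it learns one optimal (or median)
expression cutpoint per gene from right-censored survival outcomes and maps
continuous expression to binary high/low indicators, so it composes with
sklearn pipelines.  ``PrognosticScreen`` runs the full screen (cutpoint scan,
FDR/Bonferroni adjustment, univariate + confounder-adjusted Cox gates) and
behaves like a feature selector over genes.

``y`` may be a structured array with ``event``/``time`` fields (the
scikit-survival convention), a DataFrame with ``time`` and ``event`` columns,
or a ``(time, event)`` pair of vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import AnalysisDataset, COVARIATE_NAMES, ExpressionMatrix
from .screen import screen_cohort
from .selection import CandidateCriteria, apply_gates

__all__ = ["CutpointDichotomizer", "PrognosticScreen", "unpack_survival"]


def unpack_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time, event) vectors from any accepted outcome container."""
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy(int)
    arr = np.asarray(y)
    if arr.dtype.names:
        names = {n.lower(): n for n in arr.dtype.names}
        time_field = next(names[n] for n in ("time", "futime", "duration") if n in names)
        event_field = next(names[n] for n in ("event", "status", "cens") if n in names)
        return arr[time_field].astype(float), arr[event_field].astype(int)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1], int)
    raise ValueError("y must be a structured array, a time/event frame, or a (time, event) pair")


def _expression_frame(X) -> pd.DataFrame:
    """Patients x genes input as a DataFrame with usable labels."""
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, float)
    return pd.DataFrame(
        X,
        index=[f"S{i:05d}" for i in range(X.shape[0])],
        columns=[f"feature_{j}" for j in range(X.shape[1])],
    )


def _as_dataset(X, y, clinical: pd.DataFrame | None = None) -> AnalysisDataset:
    frame = _expression_frame(X)
    time, event = unpack_survival(y)
    if len(frame) != time.size:
        raise ValueError("X and y have different numbers of samples")
    clin = pd.DataFrame({"time": time, "event": event}, index=frame.index)
    for name in COVARIATE_NAMES:
        if clinical is not None and name in clinical.columns:
            clin[name] = np.asarray(clinical[name], float)
        else:
            clin[name] = 0.0  # constant -> dropped from the joint fit
    values = frame.T  # genes x patients
    mask = values.isna()
    return AnalysisDataset(clin, ExpressionMatrix(values, mask))


class CutpointDichotomizer(TransformerMixin, BaseEstimator):
    """Learn per-gene survival cutpoints; transform expression to 0/1 groups.

    Parameters
    ----------
    mode : 'optimal' slides a serial cut over the ``lo_frac``-``hi_frac``
        percentile band and picks the minimum log-rank p (falling back to the
        median cutpoint when nothing reaches ``sig_level``); 'median' always
        cuts at the median.
    """

    def __init__(
        self,
        mode: str = "optimal",
        lo_frac: float = 0.30,
        hi_frac: float = 0.70,
        sig_level: float = 0.05,
    ):
        self.mode = mode
        self.lo_frac = lo_frac
        self.hi_frac = hi_frac
        self.sig_level = sig_level

    def fit(self, X, y):
        dataset = _as_dataset(X, y)
        result = screen_cohort(
            dataset,
            mode=self.mode,
            lo_frac=self.lo_frac,
            hi_frac=self.hi_frac,
            sig_level=self.sig_level,
            fit_cox=False,
        )
        frame = _expression_frame(X)
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)
        self.results_ = result.table
        self.failures_ = result.failures
        self.cutoffs_ = result.table.set_index("gene")["cutoff_value"]
        self.support_mask_ = np.array([g in set(self.cutoffs_.index) for g in frame.columns])
        return self

    def get_support(self, indices: bool = False):
        mask = self.support_mask_
        return np.flatnonzero(mask) if indices else mask

    def transform(self, X) -> np.ndarray:
        """Binary high-expression indicators for the scannable genes.

        Entries with missing expression stay NaN.
        """
        frame = _expression_frame(X)
        if frame.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than at fit time")
        cols = frame.columns[self.support_mask_]
        values = frame[cols].to_numpy(float)
        cuts = self.cutoffs_.reindex(cols).to_numpy(float)
        out = (values > cuts[None, :]).astype(float)
        out[np.isnan(values)] = np.nan
        return out


class PrognosticScreen(BaseEstimator):
    """Full biomarker screen as a gene selector.

    ``fit(X, y, clinical=...)`` accepts an optional patients x covariates
    frame with the eight binary confounders; absent covariates simply drop
    out of the joint Cox fit.  Fitted attributes: ``results_`` (per-gene
    table), ``candidates_`` (genes passing every gate) and ``failures_``.
    """

    def __init__(
        self,
        mode: str = "optimal",
        lo_frac: float = 0.30,
        hi_frac: float = 0.70,
        sig_level: float = 0.05,
        stage: str = "bonferroni",
        fdr_threshold: float = 0.05,
        bonferroni_threshold: float = 0.05,
        hr_low: float = 0.6,
        hr_high: float = 1.8,
    ):
        self.mode = mode
        self.lo_frac = lo_frac
        self.hi_frac = hi_frac
        self.sig_level = sig_level
        self.stage = stage
        self.fdr_threshold = fdr_threshold
        self.bonferroni_threshold = bonferroni_threshold
        self.hr_low = hr_low
        self.hr_high = hr_high

    def _criteria(self) -> CandidateCriteria:
        return CandidateCriteria(
            fdr_threshold=self.fdr_threshold,
            bonferroni_threshold=self.bonferroni_threshold,
            hr_low=self.hr_low,
            hr_high=self.hr_high,
        )

    def fit(self, X, y, clinical: pd.DataFrame | None = None):
        dataset = _as_dataset(X, y, clinical)
        result = screen_cohort(
            dataset,
            mode=self.mode,
            lo_frac=self.lo_frac,
            hi_frac=self.hi_frac,
            sig_level=self.sig_level,
            cox_stage="fdr" if self.stage == "fdr" else "bonferroni",
            stage_threshold=self.fdr_threshold
            if self.stage == "fdr"
            else self.bonferroni_threshold,
        )
        frame = _expression_frame(X)
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)
        self.results_ = result.table
        self.failures_ = result.failures
        self.candidates_ = apply_gates(result.table, self._criteria(), stage=self.stage)
        selected = set(self.candidates_["gene"])
        self.support_mask_ = np.array([g in selected for g in frame.columns])
        return self

    def get_support(self, indices: bool = False):
        mask = self.support_mask_
        return np.flatnonzero(mask) if indices else mask

    def transform(self, X) -> np.ndarray:
        """Restrict an expression matrix to the candidate genes."""
        frame = _expression_frame(X)
        if frame.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than at fit time")
        return frame.to_numpy(float)[:, self.support_mask_]
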