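"""Synthetic cohorts with known per-gene truth.

The generator emulates the structure the cutpoint screen assumes: continuous
log2-scale expression per gene; a subset of genes with a *step* hazard effect
(patients above the gene's hidden q-quantile have their hazard multiplied by
the true hazard ratio); exponential event times under proportional hazards
with eight independent binary clinical covariates; independent exponential
dropout plus administrative censoring; and an optional fraction of entries
masked as not-expressed.

Defaults target a realistic overall-survival cohort for this kind of tumour
registry: baseline hazard 4e-4 events/day (mean ~6.8 years), dropout
6e-4/day and a 10-year administrative horizon, which together realize ~55-60%
censoring; covariate prevalences and log hazards loosely mirror a published
head-and-neck cohort profile.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AnalysisDataset, COVARIATE_NAMES, ExpressionMatrix

__all__ = [
    "GeneEffectSpec",
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_null_screen",
    "write_simulated",
]

DEFAULT_PREVALENCES = {
    "male": 0.73,
    "age_gt_65": 0.35,
    "t34": 0.30,
    "n_positive": 0.45,
    "m1": 0.01,
    "late_stage": 0.79,
    "margin_positive": 0.20,
    "tobacco_high": 0.50,
}

DEFAULT_LOG_HAZARDS = {
    "male": 0.05,
    "age_gt_65": 0.33,
    "t34": 0.35,
    "n_positive": 0.14,
    "m1": 0.0,
    "late_stage": 0.20,
    "margin_positive": 0.49,
    "tobacco_high": 0.31,
}


@dataclass(frozen=True)
class GeneEffectSpec:
    """Null gene, or a threshold gene with a step effect at quantile q."""

    kind: str = "null"  # "null" | "threshold"
    q: float | None = None
    hr: float | None = None

    def __post_init__(self):
        if self.kind == "threshold":
            if self.q is None or not (0 < self.q < 1):
                raise ValueError("threshold genes need a cut quantile q in (0, 1)")
            if self.hr is None or self.hr <= 0 or self.hr == 1:
                raise ValueError("threshold genes need a hazard ratio > 0, != 1")
        elif self.kind == "null":
            if self.q is not None or self.hr is not None:
                raise ValueError("null genes carry no q or hr")
        else:
            raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass
class SimConfig:
    n_patients: int = 400
    n_genes: int = 100
    #: effect specs for the first ``len(effects)`` genes; the rest are null
    effects: tuple[GeneEffectSpec, ...] = ()
    baseline_rate: float = 2e-4  # events per day
    covariate_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    covariate_log_hazards: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HAZARDS))
    admin_censor_time: float = 3652.0  # days
    dropout_rate: float = 6e-4  # per day; 0 disables dropout
    null_value_fraction: float = 0.0
    expression_location: float = 6.0  # log2 scale
    expression_scale: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not (0 <= self.null_value_fraction < 1):
            raise ValueError("null_value_fraction must be in [0, 1)")
        if len(self.effects) > self.n_genes:
            raise ValueError("more effect specs than genes")


@dataclass
class SimTruth:
    effects: dict[str, GeneEffectSpec]
    true_groups: pd.DataFrame  # threshold genes x patients, 1 = above threshold
    censoring_fraction: float

    def threshold_genes(self) -> list[str]:
        return [g for g, s in self.effects.items() if s.kind == "threshold"]


def _expected_event_fraction(cfg: SimConfig) -> float:
    lam, mu, t = cfg.baseline_rate, cfg.dropout_rate, cfg.admin_censor_time
    total = lam + mu
    return lam / total * (1.0 - np.exp(-total * t))


def simulate_dataset(config: SimConfig) -> tuple[AnalysisDataset, SimTruth]:
    """Draw one cohort; fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, g = config.n_patients, config.n_genes
    patients = pd.Index([f"P{i:05d}" for i in range(1, n + 1)], name="patient_id")
    genes = pd.Index([f"G{i:05d}" for i in range(1, g + 1)], name="gene")

    if _expected_event_fraction(config) < 0.01:
        warnings.warn("configuration implies almost no events", stacklevel=2)

    cov = pd.DataFrame(
        {
            name: rng.binomial(1, config.covariate_prevalences.get(name, 0.0), n)
            for name in COVARIATE_NAMES
        },
        index=patients,
    )

    expr = rng.normal(config.expression_location, config.expression_scale, size=(g, n))
    specs = list(config.effects) + [GeneEffectSpec()] * (g - len(config.effects))
    effects = {gene: spec for gene, spec in zip(genes, specs)}

    log_hazard = np.full(n, np.log(config.baseline_rate))
    for name in COVARIATE_NAMES:
        log_hazard += config.covariate_log_hazards.get(name, 0.0) * cov[name].to_numpy()

    truth_rows = {}
    for i, gene in enumerate(genes):
        spec = effects[gene]
        if spec.kind == "threshold":
            threshold = np.quantile(expr[i], spec.q)
            above = (expr[i] > threshold).astype(int)
            log_hazard = log_hazard + np.log(spec.hr) * above
            truth_rows[gene] = above
    true_groups = pd.DataFrame(truth_rows, index=patients).T
    true_groups.index.name = "gene"

    hazard = np.exp(log_hazard)
    t_event = rng.exponential(1.0 / hazard)
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_censor = np.minimum(t_drop, config.admin_censor_time)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    values = pd.DataFrame(expr, index=genes, columns=patients)
    mask = pd.DataFrame(False, index=genes, columns=patients)
    if config.null_value_fraction > 0:
        drop = rng.random(size=(g, n)) < config.null_value_fraction
        values = values.mask(drop)
        mask |= drop

    clinical = pd.DataFrame({"time": time, "event": event}, index=patients).join(cov)
    profiles = _profiles_from_covariates(cov, rng)
    dataset = AnalysisDataset(clinical, ExpressionMatrix(values, mask), profiles)
    truth = SimTruth(effects, true_groups, float(1.0 - event.mean()))
    return dataset, truth


def _profiles_from_covariates(cov: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Raw clinical levels consistent with the binary covariates (for IO round trips)."""
    n = len(cov)
    age = np.where(cov["age_gt_65"] == 1, 66 + rng.integers(0, 20, n), 40 + rng.integers(0, 26, n))
    packs = np.where(cov["tobacco_high"] == 1, 40 + 20 * rng.random(n), 20 * rng.random(n))
    return pd.DataFrame(
        {
            "gender": np.where(cov["male"] == 1, "male", "female"),
            "age_years": age.astype(float),
            "clinical_t": np.where(cov["t34"] == 1, "T3", "T1"),
            "clinical_n": np.where(cov["n_positive"] == 1, "N1", "N0"),
            "clinical_m": np.where(cov["m1"] == 1, "M1", "M0"),
            "stage": np.where(cov["late_stage"] == 1, "III", "I"),
            "margin": np.where(cov["margin_positive"] == 1, "positive", "negative"),
            "tobacco_pack_years": np.round(packs, 1),
        },
        index=cov.index,
    )


def simulate_null_screen(
    n_patients: int = 400,
    n_genes: int = 500,
    baseline_rate: float = 2e-4,
    dropout_rate: float = 6e-4,
    admin_censor_time: float = 3652.0,
    seed: int = 0,
) -> AnalysisDataset:
    """All-null cohort: expression independent of survival (for calibration)."""
    cfg = SimConfig(
        n_patients=n_patients,
        n_genes=n_genes,
        baseline_rate=baseline_rate,
        dropout_rate=dropout_rate,
        admin_censor_time=admin_censor_time,
        seed=seed,
    )
    dataset, _ = simulate_dataset(cfg)
    return dataset


def write_simulated(
    dataset: AnalysisDataset, truth: SimTruth, outdir: str | Path
) -> None:
    """Write the clinical/expression TSV dialects the readers accept + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clin = dataset.profiles.copy()
    clin.insert(0, "event", dataset.clinical["event"])
    clin.insert(0, "time", dataset.clinical["time"])
    clin.to_csv(outdir / "clinical.tsv", sep="\t")
    expr = dataset.expression.values.copy()
    expr[dataset.expression.null_mask] = np.nan
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    truth_json = {
        "censoring_fraction": truth.censoring_fraction,
        "effects": {
            gene: {"kind": s.kind, "q": s.q, "hr": s.hr} for gene, s in truth.effects.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2) + "\n")
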