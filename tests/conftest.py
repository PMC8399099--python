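import numpy as np
import pandas as pd
import pytest

from survscreen import ClinicalProfile, GeneEffectSpec, SimConfig, simulate_dataset

#: covariate-effect map that switches all clinical hazards off
ZERO_COVARIATE_EFFECTS = {
    "male": 0.0,
    "age_gt_65": 0.0,
    "t34": 0.0,
    "n_positive": 0.0,
    "m1": 0.0,
    "late_stage": 0.0,
    "margin_positive": 0.0,
    "tobacco_high": 0.0,
}


def write_clinical(path, rows, header=None):
    """Write a small clinical TSV; rows are dicts keyed by column name."""
    header = header or [
        "patient_id", "time", "event", "gender", "age_years", "clinical_t",
        "clinical_n", "clinical_m", "stage", "margin", "tobacco_pack_years",
    ]
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(row.get(col, "")) for col in header))
    path.write_text("\n".join(lines) + "\n")
    return path


def complete_row(pid, time=100, event=1, **overrides):
    row = {
        "patient_id": pid,
        "time": time,
        "event": event,
        "gender": "male",
        "age_years": 60,
        "clinical_t": "T2",
        "clinical_n": "N0",
        "clinical_m": "M0",
        "stage": "II",
        "margin": "negative",
        "tobacco_pack_years": 20,
    }
    row.update(overrides)
    return row


def write_expression(path, genes, patients, values):
    """values: 2-D list/array genes x patients; empty string = missing."""
    lines = ["gene\t" + "\t".join(patients)]
    for g, row in zip(genes, values):
        lines.append(g + "\t" + "\t".join("" if v is None else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def make_profile(**overrides) -> ClinicalProfile:
    base = dict(
        gender="male",
        age_years=60.0,
        clinical_t="T2",
        clinical_n="N0",
        clinical_m="M0",
        stage="II",
        margin="negative",
        tobacco_pack_years=20.0,
    )
    base.update(overrides)
    return ClinicalProfile(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """80 patients x 12 genes, one strong planted threshold gene (G00001)."""
    cfg = SimConfig(
        n_patients=80,
        n_genes=12,
        effects=(GeneEffectSpec("threshold", q=0.5, hr=4.0),),
        baseline_rate=4e-4,
        dropout_rate=2e-4,
        seed=101,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """400 patients x 30 genes with a planted effect, ~30% censoring."""
    cfg = SimConfig(
        n_patients=400,
        n_genes=30,
        effects=(GeneEffectSpec("threshold", q=0.4, hr=3.0),),
        baseline_rate=4e-4,
        dropout_rate=2e-4,
        covariate_log_hazards=dict(ZERO_COVARIATE_EFFECTS),
        seed=202,
    )
    return simulate_dataset(cfg)


def survival_frame(n, rng, event_prob=0.7, scale=100.0) -> pd.DataFrame:
    times = np.ceil(rng.exponential(scale, n))
    events = rng.binomial(1, event_prob, n)
    return pd.DataFrame({"time": times, "event": events})
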