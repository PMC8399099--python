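"""Run orchestration, structured logging, and table export.

Every exported table starts with provenance comment lines (package version
and the configuration that produced it — no timestamps, so identical runs
are byte-identical).  Plot data (volcano, cumulative-p, Kaplan-Meier) are
exported as TSV tables rather than images, keeping the core headless.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    filter_null_genes,
    merge_cohort,
    read_clinical_table,
    read_expression_matrix,
    summarize_cohort,
    ClinicalProfile,
)
from .cutpoints import candidate_positions, scan_gene
from .exceptions import ConfigurationError
from .screen import screen_cohort, gene_indicator
from .selection import CandidateCriteria, apply_gates, consensus, volcano_data
from .stats import km_estimate

__all__ = ["RunConfig", "write_table", "run_discovery", "run_validation", "load_cohort"]


@dataclass
class RunConfig:
    clinical: str = ""
    expression: str = ""
    outdir: str = "survscreen_out"
    column_map: dict = field(default_factory=dict)
    lo_frac: float = 0.30
    hi_frac: float = 0.70
    sig_level: float = 0.05
    mode: str = "optimal"  # optimal | median
    stage: str = "bonferroni"  # gate stage for candidate selection
    fdr_threshold: float = 0.05
    bonferroni_threshold: float = 0.05
    hr_low: float = 0.6
    hr_high: float = 1.8
    max_null_fraction: float = 0.30
    tobacco_split: float | None = None
    bonferroni_m: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def criteria(self) -> CandidateCriteria:
        return CandidateCriteria(
            fdr_threshold=self.fdr_threshold,
            bonferroni_threshold=self.bonferroni_threshold,
            hr_low=self.hr_low,
            hr_high=self.hr_high,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_table(frame: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """TSV with '#'-prefixed provenance header lines, then header + rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# survscreen {__version__}"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}={value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def load_cohort(config: RunConfig):
    """Read, merge and clean one cohort according to the run configuration."""
    records, invalid = read_clinical_table(config.clinical, column_map=config.column_map)
    expr = read_expression_matrix(config.expression)
    dataset, merge_report = merge_cohort(records, expr, tobacco_split=config.tobacco_split)
    filtered, filter_report = filter_null_genes(dataset.expression, config.max_null_fraction)
    dataset = dataset.with_expression(filtered)
    cleaning = {
        "invalid_clinical_rows": invalid,
        "merge": merge_report,
        "gene_filter": {k: v for k, v in filter_report.items() if k != "removed"},
        "genes_removed": [r["gene"] for r in filter_report["removed"]],
    }
    return dataset, cleaning


def _km_table(dataset, row) -> pd.DataFrame:
    """Kaplan-Meier plot table for one gene's low/high groups."""
    groups = gene_indicator(dataset, row["gene"], row["cutoff_value"])
    frames = []
    for label, value in (("low", 0.0), ("high", 1.0)):
        keep = groups == value
        curve = km_estimate(
            dataset.clinical.loc[keep, "time"], dataset.clinical.loc[keep, "event"]
        )
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time": curve.event_times,
                    "survival": curve.survival,
                    "at_risk": curve.at_risk,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _summary_frame(profiles: pd.DataFrame | None) -> pd.DataFrame:
    if profiles is None or profiles.empty:
        return pd.DataFrame(columns=["feature", "level", "count", "percent"])
    objs = [ClinicalProfile(**row) for row in profiles.to_dict("records")]
    rows = []
    for feature, levels in summarize_cohort(objs).items():
        for level, count, pct in levels:
            rows.append({"feature": feature, "level": level, "count": count, "percent": pct})
    return pd.DataFrame(rows)


def run_discovery(config: RunConfig) -> dict:
    """Full discovery workflow; returns the paths of everything written."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, cleaning = load_cohort(config)
    result = screen_cohort(
        dataset,
        mode=config.mode,
        lo_frac=config.lo_frac,
        hi_frac=config.hi_frac,
        sig_level=config.sig_level,
        cox_stage=config.stage,
        stage_threshold=config.bonferroni_threshold
        if config.stage == "bonferroni"
        else config.fdr_threshold,
        bonferroni_m=config.bonferroni_m,
    )
    candidates = apply_gates(result.table, config.criteria(), stage=config.stage)
    provenance = {k: v for k, v in config.as_dict().items() if k not in ("column_map", "outdir")}

    paths = {
        "results": outdir / "results.tsv",
        "candidates": outdir / "candidates.tsv",
        "volcano": outdir / "volcano.tsv",
        "cohort_summary": outdir / "cohort_summary.tsv",
        "runlog": outdir / "runlog.json",
    }
    write_table(result.table, paths["results"], provenance)
    write_table(candidates, paths["candidates"], provenance)
    scored = result.table[result.table["uni_hr"].notna()]
    write_table(volcano_data(scored) if not scored.empty else volcano_data(scored),
                paths["volcano"], provenance)
    write_table(_summary_frame(dataset.profiles), paths["cohort_summary"], provenance)

    for _, row in candidates.iterrows():
        gene = row["gene"]
        write_table(_km_table(dataset, row), outdir / f"km_{gene}.tsv", provenance)
        vals, null = dataset.gene_values(gene)
        keep = ~null
        grid = candidate_positions(int(keep.sum()), config.lo_frac, config.hi_frac)
        scan = scan_gene(
            vals[keep],
            dataset.times[keep],
            dataset.events[keep],
            grid=grid,
            patient_ids=dataset.patients.to_numpy()[keep],
            gene=gene,
        )
        write_table(scan.profile_frame(), outdir / f"cumulative_p_{gene}.tsv", provenance)

    failures = result.failures
    runlog = {
        "config": provenance,
        "cleaning": cleaning,
        "n_genes_screened": int(len(result.table)),
        "n_failures": int(len(failures)),
        "failure_categories": failures["category"].value_counts().to_dict()
        if not failures.empty
        else {},
        "failure_proportions": result.error_proportions,
        "excluded_genes": failures["gene"].tolist() if not failures.empty else [],
        "n_candidates": int(len(candidates)),
    }
    paths["runlog"].write_text(json.dumps(runlog, indent=2, default=str) + "\n")
    return {k: str(v) for k, v in paths.items()}


def run_validation(config: RunConfig, discovery_candidates: pd.DataFrame) -> dict:
    """Median-cutpoint validation screen + consensus with discovery candidates."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {k: v for k, v in config.as_dict().items() if k not in ("column_map", "outdir")}
    if discovery_candidates.empty:
        cons = consensus(discovery_candidates.assign(direction=None), pd.DataFrame(columns=["gene"]))
        write_table(cons, outdir / "consensus.tsv", provenance)
        return {"consensus": str(outdir / "consensus.tsv")}
    dataset, _ = load_cohort(config)
    wanted = [g for g in discovery_candidates["gene"] if g in set(dataset.genes)]
    result = screen_cohort(
        dataset,
        mode="median",
        cox_stage="raw",
        stage_threshold=1.1,  # always fit Cox for the shortlisted genes
        genes=wanted,
    )
    cons = consensus(discovery_candidates, result.table, config.criteria())
    write_table(cons, outdir / "consensus.tsv", provenance)
    write_table(result.table, outdir / "validation_results.tsv", provenance)
    return {
        "consensus": str(outdir / "consensus.tsv"),
        "validation_results": str(outdir / "validation_results.tsv"),
    }
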