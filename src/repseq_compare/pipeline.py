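"""End-to-end cohort analysis: per-sample metrics, tumor/normal overlap,
V/J usage and differential usage, paired and covariate tests, and
diversity-stratified survival.

``analyze_cohort`` is a pure function of the repertoires, the metadata and
the run parameters; ``run_pipeline`` adds I/O around it (reading clonotype
tables or simulating a cohort, and writing the TSV/JSON report bundle), so a
fixed config and inputs always reproduce the same outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clonotype_io import Repertoire, read_clonotype_table, read_metadata
from .repertoire_metrics import DEFAULT_SPECTRUM_EDGES, sample_metrics, inverse_simpson
from .overlap_analysis import overlap_rate
from .gene_usage import usage_matrix, differential_usage
from .cohort_stats import (
    DegenerateDataError,
    compare_by_covariate,
    mann_whitney_u,
    survival_stratification,
    wilcoxon_signed_rank,
)
from .synthetic_repertoires import SyntheticCohortConfig, generate_paired_cohort, write_cohort

__all__ = ["RunConfig", "PipelineError", "CohortReport", "analyze_cohort", "run_pipeline"]

log = logging.getLogger("repseq_compare")

#: per-sample metrics compared tumor vs normal across patients
_PAIRED_METRICS = (
    "productive_reads",
    "unique_clones",
    "unique_nt_clones",
    "unique_aa_clones",
    "inverse_simpson_di",
    "hec_rate_pct",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and sample."""


@dataclass
class RunConfig:
    """Serializable parameters for one pipeline run."""

    clonotype_dir: str | None = None
    metadata_path: str | None = None
    dialect: str = "native"
    simulate: bool = False
    simulate_config: SyntheticCohortConfig | None = None
    key_level: str = "nt+VJ"
    overlap_key_level: str = "nt"
    hec_threshold_percent: float = 0.1
    top_n: int = 100
    spectrum_edges: tuple[float, ...] = DEFAULT_SPECTRUM_EDGES
    usage_weighting: str = "reads"
    seed: int = 0
    out_dir: str = "repseq_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spectrum_edges"] = list(self.spectrum_edges)
        return d


@dataclass
class CohortReport:
    metrics: pd.DataFrame = field(repr=False)
    overlap: pd.DataFrame = field(repr=False)
    usage: dict[str, pd.DataFrame] = field(repr=False)
    differential: dict[str, pd.DataFrame] = field(repr=False)
    comparisons: pd.DataFrame = field(repr=False)
    survival: pd.DataFrame | None = field(repr=False)
    summary: dict = field(default_factory=dict)


def _pair_repertoires(repertoires: list[Repertoire]) -> dict[str, dict[str, Repertoire]]:
    pairs: dict[str, dict[str, Repertoire]] = {}
    for rep in repertoires:
        pairs.setdefault(rep.patient_id, {})[rep.tissue] = rep
    for pid, by_tissue in pairs.items():
        missing = {"tumor", "normal"} - set(by_tissue)
        if missing:
            raise PipelineError(f"stage pairing: patient {pid} missing {sorted(missing)} repertoire")
    return pairs


def analyze_cohort(
    repertoires: list[Repertoire], metadata: pd.DataFrame, config: RunConfig
) -> CohortReport:
    """Run every analysis stage on an in-memory cohort."""
    pairs = _pair_repertoires(repertoires)
    patients = sorted(pairs)
    meta = metadata[metadata["patient_id"].isin(patients)].reset_index(drop=True)
    if set(meta["patient_id"]) != set(patients):
        missing = sorted(set(patients) - set(meta["patient_id"]))
        raise PipelineError(f"stage metadata: no metadata row for patient(s) {missing}")

    # --- per-sample metrics -------------------------------------------------
    rows = []
    for rep in repertoires:
        try:
            values = sample_metrics(
                rep,
                hec_threshold_percent=config.hec_threshold_percent,
                top_n=config.top_n,
                spectrum_edges=config.spectrum_edges,
            )
        except Exception as exc:  # noqa: BLE001 - stage/sample context matters
            raise PipelineError(f"stage metrics: sample {rep.sample_id}: {exc}") from exc
        for metric, value in values.items():
            rows.append(
                {
                    "sample_id": rep.sample_id,
                    "patient_id": rep.patient_id,
                    "tissue": rep.tissue,
                    "metric": metric,
                    "value": value,
                }
            )
    metrics = pd.DataFrame(rows)

    def metric_by_tissue(metric: str, tissue: str) -> pd.Series:
        sel = metrics[(metrics["metric"] == metric) & (metrics["tissue"] == tissue)]
        return sel.set_index("patient_id")["value"].reindex(patients)

    # --- tumor/normal overlap ----------------------------------------------
    overlap_rows = []
    for pid in patients:
        for level in ("nt", "aa"):
            try:
                res = overlap_rate(pairs[pid]["tumor"], pairs[pid]["normal"], key_level=level)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage overlap: patient {pid}: {exc}") from exc
            overlap_rows.append(
                {
                    "patient_id": pid,
                    "key_level": level,
                    "shared_count": res.shared_count,
                    "rate_tumor": res.rate_tumor,
                    "rate_normal": res.rate_normal,
                }
            )
    overlap = pd.DataFrame(overlap_rows)

    # --- V/J usage and differential usage ----------------------------------
    tumor_reps = [pairs[p]["tumor"] for p in patients]
    normal_reps = [pairs[p]["normal"] for p in patients]
    usage: dict[str, pd.DataFrame] = {}
    differential: dict[str, pd.DataFrame] = {}
    for locus in ("V", "J"):
        for level in ("segment", "family"):
            mat = usage_matrix(repertoires, locus, level, config.usage_weighting)
            usage[f"{locus}_{level}"] = mat
        if len(patients) >= 2:
            differential[locus] = differential_usage(
                usage_matrix(tumor_reps, locus, "segment", config.usage_weighting),
                usage_matrix(normal_reps, locus, "segment", config.usage_weighting),
            )

    # --- paired tumor-vs-normal tests ---------------------------------------
    comparison_rows = []
    top_metric = f"top{config.top_n}_cumulative_pct"
    for metric in (*_PAIRED_METRICS, top_metric):
        if metric not in set(metrics["metric"]):
            continue
        tumor_vals = metric_by_tissue(metric, "tumor")
        normal_vals = metric_by_tissue(metric, "normal")
        if len(patients) < 2:
            continue
        entry = {
            "comparison": f"{metric}_tumor_vs_normal",
            "mean_tumor": float(tumor_vals.mean()),
            "sd_tumor": float(tumor_vals.std(ddof=1)),
            "mean_normal": float(normal_vals.mean()),
            "sd_normal": float(normal_vals.std(ddof=1)),
        }
        try:
            entry["p_wilcoxon"] = wilcoxon_signed_rank(
                tumor_vals.to_numpy(), normal_vals.to_numpy()
            ).p_two_tailed
        except DegenerateDataError:  # identical paired values carry no signal
            entry["p_wilcoxon"] = float("nan")
        try:
            entry["p_mann_whitney"] = mann_whitney_u(
                tumor_vals.to_numpy(), normal_vals.to_numpy()
            ).p_two_tailed
        except DegenerateDataError:
            entry["p_mann_whitney"] = float("nan")
        comparison_rows.append(entry)

    # --- clinicopathological grouping of tumor diversity --------------------
    tumor_di = metric_by_tissue("inverse_simpson_di", "tumor")
    covariate_rows = []
    for grouping in ("age", "tnm_stage", "differentiation"):
        try:
            res = compare_by_covariate(tumor_di, meta, grouping)
        except Exception as exc:  # noqa: BLE001 - degenerate groupings are data-dependent
            log.warning("covariate comparison %s skipped: %s", grouping, exc)
            continue
        covariate_rows.append(
            {
                "comparison": f"tumor_di_by_{grouping}",
                "test": res.test_name,
                "groups": "; ".join(
                    f"{g}: n={n}, {m:.4g} ± {s:.4g}" for g, (n, m, s) in res.summaries.items()
                ),
                "statistic": res.statistic,
                "p_value": res.p_two_tailed,
            }
        )
    comparisons = pd.DataFrame(comparison_rows)
    covariates = pd.DataFrame(covariate_rows)

    # --- DI-stratified survival ---------------------------------------------
    survival_table = None
    survival_summary = {}
    if {"os_time", "os_event"}.issubset(meta.columns) and len(patients) >= 2:
        meta_idx = meta.set_index("patient_id").loc[patients].reset_index()
        surv_rows = []
        for endpoint, tcol, ecol in (("os", "os_time", "os_event"), ("dfs", "dfs_time", "dfs_event")):
            if tcol not in meta.columns:
                continue
            try:
                strat = survival_stratification(tumor_di, meta_idx, tcol, ecol)
            except Exception as exc:  # noqa: BLE001
                log.warning("survival endpoint %s skipped: %s", endpoint, exc)
                continue
            for group, curve in strat.curves.items():
                tab = curve.table.copy()
                tab.insert(0, "group", group)
                tab.insert(0, "endpoint", endpoint)
                surv_rows.append(tab)
            if strat.log_rank is not None:
                survival_summary[f"log_rank_chi2_{endpoint}"] = strat.log_rank.chi_square
                survival_summary[f"log_rank_p_{endpoint}"] = strat.log_rank.p_value
        if surv_rows:
            survival_table = pd.concat(surv_rows, ignore_index=True)
        survival_summary["di_median_cutoff"] = float(np.median(tumor_di))

    summary = {
        "version": __version__,
        "n_patients": len(patients),
        "paired_comparisons": {
            row["comparison"]: {k: v for k, v in row.items() if k != "comparison"}
            for row in comparison_rows
        },
        "covariate_comparisons": {
            row["comparison"]: {"p_value": row["p_value"], "test": row["test"]}
            for row in covariate_rows
        },
        "overlap_means": {
            f"{level}_{tissue}": float(
                overlap.loc[overlap["key_level"] == level, f"rate_{tissue}"].mean()
            )
            for level in ("nt", "aa")
            for tissue in ("tumor", "normal")
        },
        "differential_usage": {
            locus: df.loc[df["significant"], "segment"].tolist()
            for locus, df in differential.items()
        },
        "survival": survival_summary,
    }
    comparisons_all = pd.concat([comparisons, covariates], ignore_index=True) if len(covariates) else comparisons
    return CohortReport(
        metrics=metrics,
        overlap=overlap,
        usage=usage,
        differential=differential,
        comparisons=comparisons_all,
        survival=survival_table,
        summary=summary,
    )


def _load_repertoires(config: RunConfig, metadata: pd.DataFrame) -> list[Repertoire]:
    """Read {patient}_T.tsv / {patient}_N.tsv for every metadata patient."""
    directory = Path(config.clonotype_dir)
    reps = []
    for pid in metadata["patient_id"]:
        for suffix, tissue in (("T", "tumor"), ("N", "normal")):
            path = directory / f"{pid}_{suffix}.tsv"
            if not path.exists():
                raise PipelineError(f"stage input: patient {pid}: missing {tissue} table {path.name}")
            reps.append(
                read_clonotype_table(
                    path,
                    config.dialect,
                    sample_id=f"{pid}_{suffix}",
                    patient_id=pid,
                    tissue=tissue,
                    key_level=config.key_level,
                )
            )
    return reps


def run_pipeline(config: RunConfig) -> CohortReport:
    """Load or simulate the cohort, analyze it, and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("repseq-compare %s starting; seed=%s", __version__, config.seed)
        if config.simulate:
            sim = config.simulate_config or SyntheticCohortConfig(seed=config.seed)
            cohort = generate_paired_cohort(sim)
            repertoires, metadata = cohort.repertoires, cohort.metadata
            write_cohort(cohort, out_dir / "simulated")
        else:
            if not config.clonotype_dir or not config.metadata_path:
                raise PipelineError("stage input: clonotype_dir and metadata_path are required")
            metadata = read_metadata(config.metadata_path)
            repertoires = _load_repertoires(config, metadata)
        report = analyze_cohort(repertoires, metadata, config)

        report.metrics.to_csv(out_dir / "sample_metrics.tsv", sep="\t", index=False)
        report.overlap.to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
        for name, mat in report.usage.items():
            tidy = mat.stack().rename_axis(["sample_id", "segment"]).reset_index(name="frequency")
            tidy.to_csv(out_dir / f"usage_{name}.tsv", sep="\t", index=False)
        for locus, diff in report.differential.items():
            diff.to_csv(out_dir / f"differential_usage_{locus}.tsv", sep="\t", index=False)
        report.comparisons.to_csv(out_dir / "cohort_comparisons.tsv", sep="\t", index=False)
        if report.survival is not None:
            report.survival.to_csv(out_dir / "survival_curves.tsv", sep="\t", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(report.summary, fh, indent=2, default=float)
        with open(out_dir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        log.info("report written to %s", out_dir)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
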