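"""End-to-end orchestration: load inputs, run every stage, write reports.

Stages run in a fixed order (capture -> coverage -> detectability ->
triage); any stage failure aborts with the failing stage named.  The
combined report carries a provenance block (config hash, library
versions), and re-running with identical inputs yields identical report
content.  Per-stage record counts are logged to serve as the audit trail.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capture import assess_capture, partition_positions_by_capture
from .coverage import (
    CATEGORY_ORDER,
    CoverageCategoryScheme,
    summarize_coverage,
)
from .io import (
    read_capture_bed,
    read_depth_table,
    read_gene_list,
    read_manifest,
    read_panel_bed,
    read_variant_catalogue,
    write_report,
)
from .triage import cohort_yield, read_findings, triage_cohort
from .variants import (
    BIN_ORDER,
    DetectabilityBins,
    detectability,
    partition_catalogue,
    unique_positions,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    panel_bed: Path
    design_bed: Path
    manifest: Path
    variants_tsv: Path
    findings_tsv: Path | None = None
    panel_genes: Path | None = None
    out_dir: Path = Path("panelcov_out")
    depth_threshold: int = 20
    min_overlap: int = 1
    summary: str = "mean"  # detectability summary statistic
    denominator: str = "captured-only"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("panel_bed", "design_bed", "manifest", "variants_tsv",
                     "findings_tsv", "panel_genes", "out_dir"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        for name in ("panel_bed", "design_bed", "manifest", "variants_tsv",
                     "findings_tsv", "panel_genes"):
            v = getattr(self, name)
            if v is not None and not v.exists():
                raise FileNotFoundError(f"{name}: {v} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def analysis_params(self) -> dict[str, str]:
        """Config fields that determine the analysis result (the output
        location and log level do not)."""
        raw = {k: str(v) for k, v in asdict(self).items()}
        raw.pop("out_dir")
        raw.pop("log_level")
        return raw

    def content_hash(self) -> str:
        blob = json.dumps(self.analysis_params(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("load-inputs")
def _load(config: RunConfig):
    genes = read_gene_list(config.panel_genes) if config.panel_genes else None
    panel = read_panel_bed(config.panel_bed, genes)
    design = read_capture_bed(config.design_bed)
    manifest = read_manifest(config.manifest)
    profiles = []
    for entry in manifest:
        if not entry.depth_path.exists():
            raise FileNotFoundError(
                f"depth file for sample {entry.sample_id!r} not found: "
                f"{entry.depth_path}"
            )
        prof = read_depth_table(entry.depth_path, panel)
        prof.sample_id = entry.sample_id
        profiles.append(prof)
    variants = read_variant_catalogue(config.variants_tsv)
    findings = (
        read_findings(config.findings_tsv, with_cohort=True)
        if config.findings_tsv
        else None
    )
    logger.info(
        "loaded %d exons, %d targets, %d samples, %d catalogue records",
        len(panel.exons), len(design), len(profiles), len(variants),
    )
    return panel, design, profiles, variants, findings


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the combined report; returns it."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel, design, profiles, variants, findings = _load(config)

    report: dict = {
        "provenance": {
            "panelcov_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config_hash": config.content_hash(),
            "config": config.analysis_params(),
        }
    }

    # ---- capture ---------------------------------------------------------
    @_stage("assess-capture")
    def _capture():
        rep = assess_capture(panel, design, config.min_overlap)
        positions = unique_positions(variants)
        partition_positions_by_capture(positions, panel, rep)
        part = partition_catalogue(variants)
        write_report(rep.exon_rows(), out / "capture_exons.tsv",
                     sort_by=["exon_id"])
        logger.info("capture: %d/%d exons captured", rep.n_captured,
                    rep.n_exons_total)
        return rep, part, positions

    cap_report, partition, positions = _capture()
    report["capture"] = {
        "n_exons_total": cap_report.n_exons_total,
        "n_captured": cap_report.n_captured,
        "n_not_captured": cap_report.n_not_captured,
        "pct_captured": cap_report.pct_captured,
        "pct_not_captured": cap_report.pct_not_captured,
        "n_positions_in_captured": cap_report.n_positions_in_captured,
        "n_positions_in_not_captured": cap_report.n_positions_in_not_captured,
        "n_positions_outside_exons": cap_report.n_positions_outside_exons,
    }
    report["catalogue"] = {
        "n_total": partition.n_total,
        "n_large_indel": partition.n_large_indel,
        "n_positional": partition.n_positional,
        "n_unique_positions": partition.n_unique_positions,
        "n_multiallelic_positions": partition.n_multiallelic_positions,
        "pct_large_indel": partition.pct_large_indel,
        "pct_positional": partition.pct_positional,
        "pct_unique_position": partition.pct_unique_position,
        "pct_multiallelic": partition.pct_multiallelic,
    }

    # ---- coverage --------------------------------------------------------
    @_stage("coverage")
    def _coverage():
        scheme = CoverageCategoryScheme(config.depth_threshold)
        summary = summarize_coverage(
            panel, profiles, scheme,
            capture_report=cap_report,
            denominator=config.denominator,
            unique_positions=positions,
        )
        write_report(summary.proportion_rows(), out / "coverage_proportions.tsv",
                     sort_by=["sample_id"])
        exon_rows = [
            {"exon_id": eid, "mean_covered_fraction": round(frac, 6)}
            for eid, frac in summary.mean_fraction_by_exon.items()
        ]
        write_report(exon_rows, out / "coverage_exons.tsv", sort_by=["exon_id"])
        return summary

    cov = _coverage()
    report["coverage"] = {
        "depth_threshold": config.depth_threshold,
        "denominator": config.denominator,
        "mean_proportions": cov.mean_proportion_dict(),
        "none_position_summary": cov.none_position_summary,
        "none_position_counts": cov.none_position_counts,
    }

    # ---- detectability ---------------------------------------------------
    @_stage("detectability")
    def _detect():
        bins = DetectabilityBins(config.depth_threshold)
        res = detectability(
            variants, profiles, panel,
            capture_report=cap_report, bins=bins, summary=config.summary,
        )
        write_report(res.per_variant_rows(), out / "detectability.tsv",
                     sort_by=["variant_id"])
        return res

    det = _detect()
    report["detectability"] = {
        "summary_statistic": config.summary,
        "n_positions_binned": len(det.positions),
        "n_captured": det.n_captured,
        "n_excluded_outside_panel": len(det.excluded),
        "n_large_indels_not_assessable": len(det.large_indels),
        "bin_counts": {b.value: det.bin_counts[b] for b in BIN_ORDER},
    }

    # ---- triage ----------------------------------------------------------
    if findings is not None:
        @_stage("triage")
        def _triage():
            finding_list, cohort = findings
            results = triage_cohort(
                finding_list, sample_ids=cohort, panel_genes=panel.genes
            )
            yields = cohort_yield(results)
            rows = [
                {"sample_id": r.sample_id, "verdict": r.verdict.value}
                for r in results
            ]
            write_report(rows, out / "triage.tsv", sort_by=["sample_id"])
            return yields

        report["triage"] = _triage()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
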