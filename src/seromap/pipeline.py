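"""End-to-end orchestration: read -> enrich -> map -> characterize -> report.

`run_analysis` is the in-memory core (objects in, objects out);
`run_pipeline` wraps it with file I/O, logging and a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import EnrichmentResult, compute_enrichment, write_enrichment_table
from .errors import ConfigError, SeromapError
from .mapping import (
    MappingResult,
    MappingSummary,
    map_peptides,
    summarize_mapping,
    write_mapping_table,
)
from .peptides import PeptideRecord, SampleDesign, read_design, read_peptide_table
from .repertoire import AntibodyClone, CloneGroup, group_clones, read_repertoire
from .stats import CloneQuant, RepertoireSummary, quantify_clones, render_report, summarize_repertoire

__all__ = ["PipelineConfig", "AnalysisResult", "load_config", "run_analysis", "run_pipeline"]

logger = logging.getLogger(__name__)

_AGGREGATES = ("mean", "median")
_CLONOTYPE_KEYS = ("cdr3_aa", "cdr3_aa_plus_v_call")


@dataclass
class PipelineConfig:
    repertoire_path: str = ""
    peptide_table_path: str = ""
    design_path: str = ""
    out_dir: str = "seromap_out"
    repertoire_format: str = "airr_tsv"
    peptide_dialect: str = "maxquant"
    fold_threshold: float = 5.0
    min_detected: int = 2
    aggregate: str = "mean"
    fold_il: bool = True
    clonotype_key: str = "cdr3_aa"
    min_cdr3_overlap: int = 1
    enzyme: str = "trypsin"
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        if self.fold_threshold <= 0:
            raise ConfigError("fold_threshold must be positive")
        if self.min_detected < 0:
            raise ConfigError("min_detected must be >= 0")
        if self.aggregate not in _AGGREGATES:
            raise ConfigError(f"aggregate must be one of {_AGGREGATES}")
        if self.clonotype_key not in _CLONOTYPE_KEYS:
            raise ConfigError(f"clonotype_key must be one of {_CLONOTYPE_KEYS}")
        if self.min_cdr3_overlap < 1:
            raise ConfigError("min_cdr3_overlap must be >= 1")
        return self


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config: flag overrides > file values > defaults."""
    values: dict = {}
    valid_keys = {f.name for f in dataclasses.fields(PipelineConfig)}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(data) - valid_keys
        if unknown:
            raise ConfigError(
                f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid_keys)}"
            )
        values.update(data)
    overrides = {k: v for k, v in overrides.items() if v is not None}
    unknown = set(overrides) - valid_keys
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid_keys)}"
        )
    values.update(overrides)
    return PipelineConfig(**values).validate()


@dataclass
class AnalysisResult:
    """All stage outputs of one in-memory run."""

    groups: list[CloneGroup]
    enrichment: list[EnrichmentResult]
    antigen_specific_peptides: list[str]
    mapping: list[MappingResult]
    mapping_summary: MappingSummary
    clone_quants: list[CloneQuant]
    repertoire_summary: RepertoireSummary


def run_analysis(
    clones: list[AntibodyClone],
    peptides: list[PeptideRecord],
    design: SampleDesign,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Enrichment filter, peptide mapping and repertoire characterization."""
    config = (config or PipelineConfig()).validate()
    groups = group_clones(clones, key=config.clonotype_key)
    enrichment = compute_enrichment(
        peptides,
        design,
        threshold=config.fold_threshold,
        min_detected=config.min_detected,
        aggregate=config.aggregate,
    )
    specific = [r.peptide for r in enrichment if r.is_antigen_specific]
    mapping = map_peptides(
        specific,
        clones,
        groups,
        fold_il_residues=config.fold_il,
        min_cdr3_overlap=config.min_cdr3_overlap,
    )
    mapping_summary = summarize_mapping(mapping)
    quants = quantify_clones(mapping, enrichment, groups)
    summary = summarize_repertoire(quants, groups, clones)
    return AnalysisResult(
        groups=groups,
        enrichment=enrichment,
        antigen_specific_peptides=specific,
        mapping=mapping,
        mapping_summary=mapping_summary,
        clone_quants=quants,
        repertoire_summary=summary,
    )


def run_pipeline(config: PipelineConfig, plots: bool = True) -> dict:
    """Full file-based run; returns (and writes) the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("seromap")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    stage = "setup"
    try:
        stage = "read_repertoire"
        clones = read_repertoire(config.repertoire_path, format=config.repertoire_format)
        stage = "read_design"
        design = read_design(config.design_path)
        stage = "read_peptide_table"
        peptides = read_peptide_table(
            config.peptide_table_path, design, dialect=config.peptide_dialect
        )
        stage = "analysis"
        result = run_analysis(clones, peptides, design, config)
        stage = "write_outputs"
        write_enrichment_table(
            result.enrichment, peptides, design, out_dir / "enrichment.tsv"
        )
        write_mapping_table(result.mapping, out_dir / "mapping.tsv")
        render_report(result.repertoire_summary, out_dir / "report", plots=plots)
        summary = result.mapping_summary
        manifest = {
            "tool": "seromap",
            "version": __version__,
            "config": dataclasses.asdict(config),
            "counts": {
                "clones": len(clones),
                "clone_groups": len(result.groups),
                "peptides": len(peptides),
                "antigen_specific_peptides": len(result.antigen_specific_peptides),
                "unmapped": summary.unmapped,
                "multi_mapped": summary.multi_mapped,
                "informative": summary.informative,
                "informative_cdr3": summary.informative_cdr3,
                "informative_other_region": summary.informative_other_region,
                "quantified_clone_groups": len(result.clone_quants),
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline finished: %s", manifest["counts"])
        return manifest
    except SeromapError:
        logger.error("pipeline failed at stage %s", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
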