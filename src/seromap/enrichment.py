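"""Elution vs flow-through enrichment and the antigen-specificity filter.

Antigen-specific antibodies are enriched by affinity chromatography: the
antigen-bound fraction ("elution") is compared against the depleted
fraction ("flow-through"). A peptide is called antigen-specific when its
aggregated elution intensity exceeds the flow-through by strictly more
than a fold-change threshold (default 5) and it is detected in at least
``min_detected`` elution replicates. A peptide present in the elution but
entirely absent from the flow-through gets fold change +inf — absence of
flow-through signal is the strongest enrichment evidence — and passes the
filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import FormatError
from .peptides import PeptideRecord, SampleDesign, validate_design

__all__ = [
    "EnrichmentResult",
    "compute_enrichment",
    "partition_by_fraction",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    peptide: str
    elution_mean: float
    flow_through_mean: float
    n_detected_elution: int
    n_detected_flow_through: int
    fold_change: float  # may be +inf
    is_antigen_specific: bool


def _aggregate(values: list[float], how: str) -> float:
    if how == "mean":
        return sum(values) / len(values)
    if how == "median":
        values = sorted(values)
        n = len(values)
        mid = n // 2
        return values[mid] if n % 2 else (values[mid - 1] + values[mid]) / 2
    raise ValueError(f"unknown aggregate: {how!r}")


def fold_change(elution: float, flow_through: float) -> float:
    if elution == 0:
        return 0.0
    if flow_through == 0:
        return math.inf
    return elution / flow_through


def compute_enrichment(
    peptides: list[PeptideRecord],
    design: SampleDesign,
    threshold: float = 5.0,
    min_detected: int = 2,
    aggregate: str = "mean",
) -> list[EnrichmentResult]:
    """Per-peptide fold change and antigen-specificity call.

    Aggregation over replicates includes zeros (a missing value is evidence
    of absence under LFQ). The specificity inequality is strict
    (fold_change > threshold). Results are sorted by descending fold change,
    then descending elution mean, then peptide.
    """
    validate_design(design)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    elution_ids = design.ids_for("elution")
    flow_ids = design.ids_for("flow_through")
    declared = set(design.sample_ids)
    results = []
    for record in peptides:
        undeclared = set(record.intensities) - declared
        if undeclared:
            raise FormatError(
                f"peptide {record.sequence}: intensity for undeclared sample(s) "
                f"{', '.join(sorted(undeclared))}"
            )
        elution = [record.intensities.get(sid, 0.0) for sid in elution_ids]
        flow = [record.intensities.get(sid, 0.0) for sid in flow_ids]
        elution_mean = _aggregate(elution, aggregate)
        flow_mean = _aggregate(flow, aggregate)
        fold = fold_change(elution_mean, flow_mean)
        n_det_elution = sum(1 for v in elution if v > 0)
        specific = fold > threshold and n_det_elution >= min_detected
        results.append(
            EnrichmentResult(
                peptide=record.sequence,
                elution_mean=elution_mean,
                flow_through_mean=flow_mean,
                n_detected_elution=n_det_elution,
                n_detected_flow_through=sum(1 for v in flow if v > 0),
                fold_change=fold,
                is_antigen_specific=specific,
            )
        )
    results.sort(key=lambda r: (-r.fold_change, -r.elution_mean, r.peptide))
    return results


def partition_by_fraction(
    peptides: list[PeptideRecord], design: SampleDesign
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Peptide lists per fraction: detected (>0) in >= 1 replicate of that fraction."""
    validate_design(design)
    elution_ids = design.ids_for("elution")
    flow_ids = design.ids_for("flow_through")
    elution = [
        p for p in peptides if any(p.intensities.get(sid, 0.0) > 0 for sid in elution_ids)
    ]
    flow = [p for p in peptides if any(p.intensities.get(sid, 0.0) > 0 for sid in flow_ids)]
    return elution, flow


def write_enrichment_table(
    results: list[EnrichmentResult],
    peptides: list[PeptideRecord],
    design: SampleDesign,
    path: str | Path,
) -> Path:
    """Write the enrichment TSV (fold +inf serialized as "Inf")."""
    path = Path(path)
    by_sequence = {p.sequence: p for p in peptides}
    rows = []
    for r in results:
        record = by_sequence[r.peptide]
        row: dict = {"peptide": r.peptide}
        for sid in design.sample_ids:
            row[f"intensity_{sid}"] = record.intensities.get(sid, 0.0)
        row.update(
            elution_mean=r.elution_mean,
            flow_through_mean=r.flow_through_mean,
            n_detected_elution=r.n_detected_elution,
            n_detected_flow_through=r.n_detected_flow_through,
            fold_change="Inf" if math.isinf(r.fold_change) else r.fold_change,
            is_antigen_specific=r.is_antigen_specific,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
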