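"""MaxQuant-style peptide table parsing and experimental-design binding.

The quantitative input is a peptide intensity table in the MaxQuant
``peptides.txt`` dialect (one row per peptide, one ``LFQ intensity <sample>``
or ``Intensity <sample>`` column per MS run), together with a sample design
that labels every run as an elution or flow-through replicate. Label-free
quantification across fractions requires at least two replicates per
fraction, which :func:`validate_design` enforces.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import DesignError, FormatError, ValidationError

__all__ = [
    "SampleInfo",
    "SampleDesign",
    "PeptideRecord",
    "validate_design",
    "read_design",
    "write_design",
    "read_peptide_table",
    "write_peptide_table",
]

FRACTIONS = ("elution", "flow_through")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    fraction: str  # "elution" or "flow_through"
    replicate: int


@dataclass(frozen=True)
class SampleDesign:
    """Which MS runs exist and which affinity-chromatography fraction each is."""

    samples: tuple[SampleInfo, ...]

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    def ids_for(self, fraction: str) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples if s.fraction == fraction)


@dataclass
class PeptideRecord:
    """One identified peptide with per-sample intensities (missing stored as 0)."""

    sequence: str
    intensities: dict[str, float]
    source_proteins: str | None = None

    def validate(self) -> None:
        if not self.sequence:
            raise ValidationError("empty peptide sequence")
        for sample_id, value in self.intensities.items():
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"peptide {self.sequence}: intensity for {sample_id} is {value!r}"
                )


def validate_design(design: SampleDesign) -> SampleDesign:
    """Check replicate counts; LFQ comparison needs >= 2 replicates per fraction."""
    ids = [s.sample_id for s in design.samples]
    if len(ids) != len(set(ids)):
        raise DesignError("duplicate sample_ids in design")
    for sample in design.samples:
        if sample.fraction not in FRACTIONS:
            raise DesignError(
                f"sample {sample.sample_id}: fraction must be one of {FRACTIONS}"
            )
    for fraction in FRACTIONS:
        n = len(design.ids_for(fraction))
        if n < 2:
            raise DesignError(
                f"fraction {fraction!r} has {n} replicate(s); at least 2 are required"
            )
    return design


def _design_from_rows(rows: list[dict]) -> SampleDesign:
    samples = []
    for row in rows:
        samples.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                fraction=str(row["fraction"]),
                replicate=int(row["replicate"]),
            )
        )
    return SampleDesign(samples=tuple(samples))


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design from a YAML (list of mappings) or TSV sidecar."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"design file not found: {path}")
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if isinstance(data, dict):
            data = data.get("samples", data)
        if not isinstance(data, list):
            raise FormatError(f"{path}: expected a list of sample mappings")
        rows = data
    else:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("sample_id", "fraction", "replicate") if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
        rows = df.to_dict(orient="records")
    return validate_design(_design_from_rows(rows))


def write_design(design: SampleDesign, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "samples": [
            {"sample_id": s.sample_id, "fraction": s.fraction, "replicate": s.replicate}
            for s in design.samples
        ]
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def _intensity_column(columns: set[str], sample_id: str) -> str:
    # LFQ intensities preferred over raw intensities when both are present.
    for prefix in ("LFQ intensity ", "Intensity "):
        if prefix + sample_id in columns:
            return prefix + sample_id
    raise FormatError(f"sample {sample_id} not found in peptide table header")


def _read_maxquant(path: Path, design: SampleDesign) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "Sequence" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'Sequence'")
    columns = set(df.columns)
    col_for = {sid: _intensity_column(columns, sid) for sid in design.sample_ids}
    records: list[PeptideRecord] = []
    for row in df.to_dict(orient="records"):
        flagged = any(
            str(row.get(flag, "")).strip() == "+"
            for flag in ("Reverse", "Potential contaminant")
        )
        if flagged:
            continue
        intensities = {}
        for sid, col in col_for.items():
            raw = row.get(col)
            value = 0.0 if raw is None or str(raw).strip() in ("", "nan", "NaN") else float(raw)
            intensities[sid] = value
        proteins = row.get("Proteins")
        if proteins is not None and str(proteins) == "nan":
            proteins = None
        records.append(
            PeptideRecord(
                sequence=str(row["Sequence"]).strip(),
                intensities=intensities,
                source_proteins=proteins,
            )
        )
    return records


def _read_long(path: Path, design: SampleDesign) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("peptide", "sample_id", "intensity") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    declared = set(design.sample_ids)
    undeclared = set(df["sample_id"].astype(str)) - declared
    if undeclared:
        raise FormatError(f"{path}: undeclared sample(s): {', '.join(sorted(undeclared))}")
    if df.duplicated(subset=["peptide", "sample_id"]).any():
        raise FormatError(f"{path}: duplicate (peptide, sample_id) rows")
    records = []
    for peptide, sub in df.groupby("peptide", sort=True):
        per_sample = dict(zip(sub["sample_id"].astype(str), sub["intensity"].astype(float)))
        intensities = {sid: float(per_sample.get(sid, 0.0)) for sid in design.sample_ids}
        intensities = {k: (0.0 if v != v else v) for k, v in intensities.items()}
        records.append(PeptideRecord(sequence=str(peptide), intensities=intensities))
    return records


def read_peptide_table(
    path: str | Path, design: SampleDesign, dialect: str = "maxquant"
) -> list[PeptideRecord]:
    """Parse a peptide intensity table and bind intensities to declared samples.

    MaxQuant dialect: rows flagged ``Reverse`` or ``Potential contaminant``
    ("+") are dropped; missing intensity cells become 0. Duplicate peptide
    sequences are an error (quantification would be ambiguous).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"peptide table not found: {path}")
    if dialect == "maxquant":
        records = _read_maxquant(path, design)
    elif dialect == "long":
        records = _read_long(path, design)
    else:
        raise ValueError(f"unknown peptide table dialect: {dialect!r}")
    counts = Counter(r.sequence for r in records)
    dupes = {s for s, n in counts.items() if n > 1}
    if dupes:
        raise FormatError(
            f"{path}: duplicate peptide sequence(s): {', '.join(sorted(dupes)[:5])}"
        )
    for record in records:
        record.validate()
    return records


def write_peptide_table(
    records: list[PeptideRecord],
    design: SampleDesign,
    path: str | Path,
    dialect: str = "maxquant",
) -> Path:
    path = Path(path)
    if dialect == "maxquant":
        rows = []
        for r in records:
            row: dict = {"Sequence": r.sequence, "Reverse": "", "Potential contaminant": ""}
            for sid in design.sample_ids:
                row[f"LFQ intensity {sid}"] = r.intensities.get(sid, 0.0)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif dialect == "long":
        rows = [
            {"peptide": r.sequence, "sample_id": sid, "intensity": r.intensities.get(sid, 0.0)}
            for r in records
            for sid in design.sample_ids
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown peptide table dialect: {dialect!r}")
    return path
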