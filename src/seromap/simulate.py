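"""Fully in-silico Ig-Seq experiments with known ground truth.

The simulator emulates the experimental design the pipeline assumes: a
personal BCR-Seq repertoire at the amino-acid level, its tryptic peptides,
and replicate label-free intensities for an elution / flow-through
affinity-chromatography experiment in which a known subset of clones is
antigen-specific.

Clones are built as shared framework scaffolds (FR1..FR3 constant across
the repertoire, CDR1/CDR2 varying per scaffold) with a random CDR3 insert
per clone, so framework-derived peptides multi-map across clones while
CDR3-derived peptides are informative — the unmapped / multi-mapped /
informative trichotomy is exercised by construction, not vacuously.
CDR3 inserts avoid K, R and P so that each clone's CDR3 sits inside a
single tryptic peptide delimited by lysines planted in the flanking
framework; every antigen-specific clone is therefore recoverable through
an informative CDR3 peptide.

Intensities follow a log-normal LFQ model: each (peptide, origin clone)
pair contributes a base-10 log-normal component; flow-through intensity is
the component sum and elution multiplies components from antigen-specific
origins by ``enrichment_fold``. Replicates apply multiplicative log-normal
noise and Bernoulli detection dropout. All draws go through one seeded
generator, so fixtures are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .digestion import digest, get_enzyme
from .errors import ConfigError
from .peptides import (
    PeptideRecord,
    SampleDesign,
    SampleInfo,
    write_design,
    write_peptide_table,
)
from .repertoire import AntibodyClone, write_repertoire

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_repertoire",
    "simulate_peptide_table",
    "simulate_experiment",
    "write_fixture",
]

# Germline-like scaffold segments; FR3 ends in K and FR4 carries an early K
# so tryptic cleavage brackets the CDR3 insert.
_FR1 = "EVQLVESGGGLVQPGGSLRLSCAAS"
_FR2 = "WVRQAPGKGLEWVS"
_FR3 = "RFTISRDNSKNTLYLQMNSLRAEDTAVYYCAK"
_FR4 = "WGQGTKVTVSS"

# CDR residue pool: no K/R (keeps CDR3 inside one tryptic peptide) and no P
# (avoids blocking the planted cleavage sites).
_CDR_ALPHABET = "ACDEFGHLMNQSTVWY"
_CDR12_ALPHABET = _CDR_ALPHABET

_DEFAULT_ISOTYPES = ("IgG1", "IgG2", "IgG3", "IgA1", "IgM")
_DEFAULT_V = ("IGHV1-2", "IGHV1-69", "IGHV3-23", "IGHV3-30", "IGHV4-34", "IGHV5-51")
_DEFAULT_D = ("IGHD2-2", "IGHD3-10", "IGHD3-22", "IGHD6-19")
_DEFAULT_J = ("IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the in-silico experiment; defaults are the study conditions."""

    n_clones: int = 100
    n_antigen_specific: int = 10
    cdr3_length_range: tuple[int, int] = (8, 22)
    framework_template_count: int = 5
    isotype_labels: tuple[str, ...] = _DEFAULT_ISOTYPES
    v_labels: tuple[str, ...] = _DEFAULT_V
    d_labels: tuple[str, ...] = _DEFAULT_D
    j_labels: tuple[str, ...] = _DEFAULT_J
    n_replicates_per_fraction: int = 3
    log_intensity_mean: float = 7.0
    log_intensity_sd: float = 0.6
    enrichment_fold: float = 20.0
    noise_sd: float = 0.1
    detection_dropout: float = 0.05
    enzyme: str = "trypsin"
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_clones < 1:
            raise ConfigError("n_clones must be >= 1")
        if not 0 <= self.n_antigen_specific <= self.n_clones:
            raise ConfigError("n_antigen_specific must be in [0, n_clones]")
        lo, hi = self.cdr3_length_range
        if not 1 <= lo <= hi:
            raise ConfigError("cdr3_length_range must satisfy 1 <= lo <= hi")
        if self.framework_template_count < 1:
            raise ConfigError("framework_template_count must be >= 1")
        if self.n_replicates_per_fraction < 2:
            raise ConfigError("n_replicates_per_fraction must be >= 2")
        if self.enrichment_fold <= 0:
            raise ConfigError("enrichment_fold must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.detection_dropout < 1:
            raise ConfigError("detection_dropout must be in [0, 1)")
        return self


@dataclass
class GroundTruth:
    """What was planted: which clonotypes are specific and where peptides come from."""

    specific_group_keys: set[str] = field(default_factory=set)
    specific_record_ids: set[str] = field(default_factory=set)
    peptide_origin: dict[str, set[str]] = field(default_factory=dict)
    planted_folds: dict[str, float] = field(default_factory=dict)


def _random_cdr(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def simulate_repertoire(config: SimulationConfig) -> tuple[list[AntibodyClone], GroundTruth]:
    """Generate a repertoire of scaffold+CDR3 clones and mark the specific subset."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    scaffolds = [
        (_random_cdr(rng, 8, _CDR12_ALPHABET), _random_cdr(rng, 8, _CDR12_ALPHABET))
        for _ in range(config.framework_template_count)
    ]
    lo, hi = config.cdr3_length_range
    clones: list[AntibodyClone] = []
    seen_cdr3: set[str] = set()
    for i in range(config.n_clones):
        cdr1, cdr2 = scaffolds[int(rng.integers(0, len(scaffolds)))]
        while True:
            cdr3 = _random_cdr(rng, int(rng.integers(lo, hi + 1)), _CDR_ALPHABET)
            if cdr3 not in seen_cdr3:
                seen_cdr3.add(cdr3)
                break
        segments = (_FR1, cdr1, _FR2, cdr2, _FR3, cdr3, _FR4)
        names = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
        bounds: dict[str, tuple[int, int]] = {}
        offset = 0
        for name, segment in zip(names, segments):
            bounds[name] = (offset, offset + len(segment))
            offset += len(segment)
        clone = AntibodyClone(
            record_id=f"c{i:04d}",
            sequence_aa="".join(segments),
            cdr3_aa=cdr3,
            isotype=str(rng.choice(config.isotype_labels)),
            v_call=str(rng.choice(config.v_labels)),
            d_call=str(rng.choice(config.d_labels)),
            j_call=str(rng.choice(config.j_labels)),
            read_count=int(rng.geometric(0.15)),
            region_bounds=bounds,
        )
        clone.validate()
        clones.append(clone)
    specific_idx = rng.choice(config.n_clones, size=config.n_antigen_specific, replace=False)
    truth = GroundTruth(
        specific_group_keys={clones[i].cdr3_aa for i in specific_idx},
        specific_record_ids={clones[i].record_id for i in specific_idx},
    )
    return clones, truth


def simulate_peptide_table(
    clones: list[AntibodyClone],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[PeptideRecord], SampleDesign, GroundTruth]:
    """Tryptic peptides of the repertoire with replicate LFQ intensities.

    Returns the peptide records, the replicate design, and the completed
    ground truth (peptide origins and planted fold changes).
    """
    config.validate()
    # Independent stream from the repertoire stage, still derived from the seed.
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    rule = get_enzyme(config.enzyme)
    origin: dict[str, set[str]] = {}
    for clone in clones:
        for fragment in digest(clone.sequence_aa, rule):
            origin.setdefault(fragment.peptide, set()).add(clone.record_id)
    n = config.n_replicates_per_fraction
    design = SampleDesign(
        samples=tuple(
            [SampleInfo(f"E{r}", "elution", r) for r in range(1, n + 1)]
            + [SampleInfo(f"FT{r}", "flow_through", r) for r in range(1, n + 1)]
        )
    )
    records: list[PeptideRecord] = []
    planted_folds: dict[str, float] = {}
    for peptide in sorted(origin):
        flow_total = 0.0
        elution_total = 0.0
        for record_id in sorted(origin[peptide]):
            base = 10.0 ** rng.normal(config.log_intensity_mean, config.log_intensity_sd)
            flow_total += base
            elution_total += base * (
                config.enrichment_fold if record_id in truth.specific_record_ids else 1.0
            )
        planted_folds[peptide] = elution_total / flow_total
        intensities: dict[str, float] = {}
        for sample in design.samples:
            total = elution_total if sample.fraction == "elution" else flow_total
            value = total * 10.0 ** rng.normal(0.0, config.noise_sd)
            if rng.random() < config.detection_dropout:
                value = 0.0
            intensities[sample.sample_id] = value
        records.append(PeptideRecord(sequence=peptide, intensities=intensities))
    complete = GroundTruth(
        specific_group_keys=set(truth.specific_group_keys),
        specific_record_ids=set(truth.specific_record_ids),
        peptide_origin=origin,
        planted_folds=planted_folds,
    )
    return records, design, complete


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[AntibodyClone], list[PeptideRecord], SampleDesign, GroundTruth]:
    """Repertoire + peptide table in one call."""
    clones, truth = simulate_repertoire(config)
    records, design, truth = simulate_peptide_table(clones, truth, config)
    return clones, records, design, truth


def write_fixture(
    out_dir: str | Path,
    clones: list[AntibodyClone],
    peptides: list[PeptideRecord],
    design: SampleDesign,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Emit a complete fixture directory: repertoire TSV, MaxQuant-dialect
    peptide table, design YAML, and ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "repertoire": out_dir / "repertoire.tsv",
        "peptides": out_dir / "peptides.txt",
        "design": out_dir / "design.yaml",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_repertoire(clones, paths["repertoire"], format="airr_tsv")
    write_peptide_table(peptides, design, paths["peptides"], dialect="maxquant")
    write_design(design, paths["design"])
    payload = {
        "specific_group_keys": sorted(truth.specific_group_keys),
        "specific_record_ids": sorted(truth.specific_record_ids),
        "peptide_origin": {p: sorted(ids) for p, ids in sorted(truth.peptide_origin.items())},
        "planted_folds": {p: truth.planted_folds[p] for p in sorted(truth.planted_folds)},
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=2, sort_keys=False))
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        specific_group_keys=set(data["specific_group_keys"]),
        specific_record_ids=set(data["specific_record_ids"]),
        peptide_origin={p: set(ids) for p, ids in data["peptide_origin"].items()},
        planted_folds=dict(data["planted_folds"]),
    )
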