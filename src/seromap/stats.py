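"""Characterization of the antigen-specific clone set.

Once informative peptides have pinned antigen-specific serum antibodies to
clonotype groups, the recovered clone set is summarized the way repertoire
studies conventionally report it: isotype distribution, CDR3 length
distribution, V/D/J gene usage (single and combined), and the proteomic
intensity of each clonotype against its BCR-Seq read frequency. Clone
intensity is the sum of the elution-mean intensities of the informative
peptides assigned to the group — the standard label-free peptide-to-protein
roll-up (mean available as an option). All distributions are computed over
the antigen-specific groups only, not the full repertoire.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .enrichment import EnrichmentResult
from .errors import ValidationError
from .mapping import CLASS_INFORMATIVE, MappingResult
from .repertoire import AntibodyClone, CloneGroup

__all__ = [
    "CloneQuant",
    "RepertoireSummary",
    "quantify_clones",
    "summarize_repertoire",
    "render_report",
]

logger = logging.getLogger(__name__)

SINGLE_USAGE = ("v", "d", "j")
COMBINED_USAGE = ("vd", "vj", "dj", "vdj")


@dataclass(frozen=True)
class CloneQuant:
    group_key: str
    summed_intensity: float
    n_informative_peptides: int
    n_cdr3_peptides: int
    bcr_frequency: float  # group reads / total repertoire reads


@dataclass
class RepertoireSummary:
    isotype_distribution: dict[str, float]
    cdr3_length_histogram: dict[int, int]
    gene_usage: dict[str, dict[str, int]]  # keys v, d, j, vd, vj, dj, vdj
    clone_quants: list[CloneQuant]
    n_groups_missing_d: int = 0


def quantify_clones(
    mapping: list[MappingResult],
    enrichment: list[EnrichmentResult],
    groups: list[CloneGroup],
    roll_up: str = "sum",
) -> list[CloneQuant]:
    """Roll informative-peptide elution intensities up to clonotype groups.

    Only informative peptides contribute; each contributes its elution mean
    to exactly its one group. Groups without informative evidence are
    omitted. BCR frequency is the group's read count over the total reads of
    the whole repertoire.
    """
    if roll_up not in ("sum", "mean"):
        raise ValueError(f"unknown roll_up: {roll_up!r}")
    elution_mean = {r.peptide: r.elution_mean for r in enrichment}
    known_groups = {g.group_key: g for g in groups}
    total_reads = sum(g.total_read_count for g in groups)
    intensities: dict[str, list[float]] = {}
    n_cdr3: Counter[str] = Counter()
    for result in mapping:
        if result.classification != CLASS_INFORMATIVE:
            continue
        (group_key,) = result.clone_groups_hit
        if group_key not in known_groups:
            raise ValidationError(
                f"informative peptide {result.peptide} references unknown group {group_key!r}"
            )
        intensities.setdefault(group_key, []).append(elution_mean.get(result.peptide, 0.0))
        if result.informative_cdr3:
            n_cdr3[group_key] += 1
    quants = []
    for group_key in sorted(intensities):
        values = intensities[group_key]
        rolled = sum(values) if roll_up == "sum" else sum(values) / len(values)
        quants.append(
            CloneQuant(
                group_key=group_key,
                summed_intensity=rolled,
                n_informative_peptides=len(values),
                n_cdr3_peptides=n_cdr3[group_key],
                bcr_frequency=known_groups[group_key].total_read_count / total_reads,
            )
        )
    return quants


def summarize_repertoire(
    quants: list[CloneQuant],
    groups: list[CloneGroup],
    clones: list[AntibodyClone],
) -> RepertoireSummary:
    """Distributions over the antigen-specific clonotype groups.

    CDR3 length comes from the group's clonal CDR3; isotype and gene labels
    from the group representative. Groups lacking a D call are excluded from
    D-containing usage tables and counted separately. Combined usage keys
    join gene labels with "|".
    """
    by_key = {g.group_key: g for g in groups}
    specific = [by_key[q.group_key] for q in quants]

    isotypes = Counter(g.representative_isotype for g in specific)
    n = len(specific)
    isotype_distribution = {k: isotypes[k] / n for k in sorted(isotypes)} if n else {}

    # Under the default clonotype key the group key IS the CDR3 sequence;
    # fall back to the longest member CDR3 otherwise.
    lengths: Counter[int] = Counter()
    clone_by_id = {c.record_id: c for c in clones}
    for group in specific:
        member_cdr3s = {clone_by_id[m].cdr3_aa for m in group.members if m in clone_by_id}
        cdr3 = next(iter(member_cdr3s)) if len(member_cdr3s) == 1 else group.group_key
        lengths[len(cdr3)] += 1

    usage: dict[str, dict[str, int]] = {}
    with_d = [g for g in specific if g.representative_d_call is not None]
    labels = {
        "v": [(g.representative_v_call,) for g in specific],
        "d": [(g.representative_d_call,) for g in with_d],
        "j": [(g.representative_j_call,) for g in specific],
        "vd": [(g.representative_v_call, g.representative_d_call) for g in with_d],
        "vj": [(g.representative_v_call, g.representative_j_call) for g in specific],
        "dj": [(g.representative_d_call, g.representative_j_call) for g in with_d],
        "vdj": [
            (g.representative_v_call, g.representative_d_call, g.representative_j_call)
            for g in with_d
        ],
    }
    for table, tuples in labels.items():
        counts = Counter("|".join(t) for t in tuples)
        usage[table] = {k: counts[k] for k in sorted(counts)}

    return RepertoireSummary(
        isotype_distribution=isotype_distribution,
        cdr3_length_histogram={k: lengths[k] for k in sorted(lengths)},
        gene_usage=usage,
        clone_quants=quants,
        n_groups_missing_d=len(specific) - len(with_d),
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def summary_tables(summary: RepertoireSummary) -> dict[str, pd.DataFrame]:
    """The TSV tables behind every report plot, keyed by file stem."""
    tables: dict[str, pd.DataFrame] = {}
    tables["isotype_distribution"] = pd.DataFrame(
        [{"isotype": k, "proportion": v} for k, v in summary.isotype_distribution.items()],
        columns=["isotype", "proportion"],
    )
    tables["cdr3_length"] = pd.DataFrame(
        [{"length": k, "count": v} for k, v in summary.cdr3_length_histogram.items()],
        columns=["length", "count"],
    )
    for table in (*SINGLE_USAGE, *COMBINED_USAGE):
        tables[f"usage_{table}"] = pd.DataFrame(
            [{"genes": k, "count": v} for k, v in summary.gene_usage[table].items()],
            columns=["genes", "count"],
        )
    tables["intensity_vs_frequency"] = pd.DataFrame(
        [
            {
                "group_key": q.group_key,
                "summed_intensity": q.summed_intensity,
                "n_informative_peptides": q.n_informative_peptides,
                "n_cdr3_peptides": q.n_cdr3_peptides,
                "bcr_frequency": q.bcr_frequency,
            }
            for q in summary.clone_quants
        ],
        columns=[
            "group_key",
            "summed_intensity",
            "n_informative_peptides",
            "n_cdr3_peptides",
            "bcr_frequency",
        ],
    )
    return tables


def render_report(
    summary: RepertoireSummary, out_dir: str | Path, plots: bool = True
) -> dict[str, Path]:
    """Write one TSV per table plus a static image per plot.

    File names are deterministic. On an empty summary only header-bearing
    TSVs are produced and a warning is logged.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tables = summary_tables(summary)
    for stem, df in tables.items():
        path = out_dir / f"{stem}.tsv"
        _write_tsv(df, path)
        written[stem] = path
    if not summary.clone_quants:
        logger.warning("empty repertoire summary: no plots rendered")
        return written
    if plots:
        written.update(_render_plots(tables, out_dir))
    return written


def _render_plots(tables: dict[str, pd.DataFrame], out_dir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: dict[str, Path] = {}

    def save(fig, stem: str) -> None:
        path = out_dir / f"{stem}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written[f"{stem}_plot"] = path

    empty = pd.DataFrame()
    iso = tables.get("isotype_distribution", empty)
    if len(iso):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.pie(iso["proportion"], labels=iso["isotype"], autopct="%.0f%%")
        ax.set_title("Isotype distribution")
        save(fig, "isotype_distribution")

    cdr3 = tables.get("cdr3_length", empty)
    if len(cdr3):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar(cdr3["length"], cdr3["count"], color="#4878a8")
        ax.set_xlabel("CDR3 length (aa)")
        ax.set_ylabel("clone groups")
        ax.set_title("CDR3 length distribution")
        fig.tight_layout()
        save(fig, "cdr3_length")

    for table in (*SINGLE_USAGE, *COMBINED_USAGE):
        df = tables.get(f"usage_{table}", empty)
        if not len(df):
            continue
        fig, ax = plt.subplots(figsize=(max(4, 0.45 * len(df)), 3.5))
        ax.bar(df["genes"], df["count"], color="#6aa84f")
        ax.set_ylabel("clone groups")
        ax.set_title(f"{table.upper()} gene usage")
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        save(fig, f"usage_{table}")

    quant = tables.get("intensity_vs_frequency", empty)
    if len(quant):
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.scatter(quant["bcr_frequency"], quant["summed_intensity"], s=18, alpha=0.8)
        ax.set_xlabel("BCR-Seq frequency")
        ax.set_ylabel("summed elution intensity")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_title("Proteomic intensity vs repertoire frequency")
        fig.tight_layout()
        save(fig, "intensity_vs_frequency")
    return written
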