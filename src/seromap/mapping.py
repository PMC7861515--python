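"""Map antigen-specific peptides onto the BCR-Seq repertoire.

Every occurrence of each peptide across all clone sequences is found by a
multi-pattern Aho-Corasick scan, so total work scales with repertoire
length plus hits rather than peptides x clones. Because LC-MS/MS cannot
distinguish isoleucine from leucine, both the peptides and the clone
sequences are folded to a single I/L symbol before matching by default.

Peptides are then classified: *unmapped* (no occurrence anywhere),
*multi-mapped* (occurrences in two or more clonotype groups), or
*informative* (all occurrences within a single clonotype group — the
peptide pins down one antibody clone). Uniqueness is judged at the group
level: a peptide hitting several records that share one CDR3 clonotype is
still informative. Each hit is localized against the clone's region
annotation; informative peptides overlapping CDRH3 give the strongest
serum-antibody-to-clone link.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

from .repertoire import AA_ALPHABET, AntibodyClone, CloneGroup

__all__ = [
    "PeptideHit",
    "MappingResult",
    "MappingSummary",
    "map_peptides",
    "summarize_mapping",
    "write_mapping_table",
]

logger = logging.getLogger(__name__)

_IL_FOLD = str.maketrans("I", "L")

CLASS_UNMAPPED = "unmapped"
CLASS_MULTI = "multi_mapped"
CLASS_INFORMATIVE = "informative"


def fold_il(sequence: str) -> str:
    """Collapse isoleucine onto leucine (indistinguishable by mass)."""
    return sequence.translate(_IL_FOLD)


@dataclass(frozen=True)
class PeptideHit:
    record_id: str
    start: int
    end: int
    regions_overlapped: frozenset[str]
    overlaps_cdr3: bool


@dataclass(frozen=True)
class MappingResult:
    peptide: str
    hits: tuple[PeptideHit, ...]
    clone_groups_hit: frozenset[str]
    classification: str
    informative_cdr3: bool


@dataclass(frozen=True)
class MappingSummary:
    unmapped: int
    multi_mapped: int
    informative: int
    informative_cdr3: int
    informative_other_region: int

    @property
    def total(self) -> int:
        return self.unmapped + self.multi_mapped + self.informative


class AhoCorasick:
    """Multi-pattern exact substring matcher (goto/fail automaton)."""

    def __init__(self, patterns: list[str]):
        self.patterns = patterns
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[int]] = [[]]
        for index, pattern in enumerate(patterns):
            node = 0
            for ch in pattern:
                nxt = self._goto[node].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._fail.append(0)
                    self._out.append([])
                    nxt = len(self._goto) - 1
                    self._goto[node][ch] = nxt
                node = nxt
            self._out[node].append(index)
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                link = self._goto[f].get(ch, 0)
                self._fail[child] = link if link != child else 0
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def scan(self, text: str):
        """Yield (pattern_index, start) for every occurrence in text."""
        node = 0
        goto, fail, out, patterns = self._goto, self._fail, self._out, self.patterns
        for position, ch in enumerate(text):
            while node and ch not in goto[node]:
                node = fail[node]
            node = goto[node].get(ch, 0)
            for index in out[node]:
                yield index, position + 1 - len(patterns[index])


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def map_peptides(
    peptides: list[str],
    clones: list[AntibodyClone],
    groups: list[CloneGroup],
    fold_il_residues: bool = True,
    min_cdr3_overlap: int = 1,
) -> list[MappingResult]:
    """Find all occurrences of each peptide and classify it.

    ``min_cdr3_overlap`` is the number of residues a hit must share with the
    clone's CDR3 interval to count as CDR3-localized. Peptides containing
    residues outside the amino-acid alphabet are reported unmapped with a
    warning. Results preserve the input peptide order.
    """
    record_to_group = {
        record_id: group.group_key for group in groups for record_id in group.members
    }
    transform = fold_il if fold_il_residues else (lambda s: s)
    valid: list[str] = []
    invalid: set[str] = set()
    for peptide in peptides:
        if not peptide or set(peptide) - AA_ALPHABET:
            logger.warning("peptide %r contains invalid residues; reported unmapped", peptide)
            invalid.add(peptide)
        else:
            valid.append(peptide)
    # Distinct folded patterns; I/L folding may merge several input peptides.
    pattern_to_peptides: dict[str, list[str]] = {}
    for peptide in valid:
        pattern_to_peptides.setdefault(transform(peptide), []).append(peptide)
    patterns = sorted(pattern_to_peptides)
    automaton = AhoCorasick(patterns)
    hits_by_peptide: dict[str, list[PeptideHit]] = {p: [] for p in peptides}
    for clone in clones:
        text = transform(clone.sequence_aa)
        cdr3_bounds = clone.region_bounds["CDR3"]
        for index, start in automaton.scan(text):
            pattern = patterns[index]
            end = start + len(pattern)
            regions = frozenset(
                region
                for region, bounds in clone.region_bounds.items()
                if _interval_overlap((start, end), bounds) >= 1
            )
            overlaps_cdr3 = _interval_overlap((start, end), cdr3_bounds) >= min_cdr3_overlap
            hit = PeptideHit(
                record_id=clone.record_id,
                start=start,
                end=end,
                regions_overlapped=regions,
                overlaps_cdr3=overlaps_cdr3,
            )
            for peptide in pattern_to_peptides[pattern]:
                hits_by_peptide[peptide].append(hit)
    results = []
    for peptide in peptides:
        hits = tuple(
            sorted(hits_by_peptide[peptide], key=lambda h: (h.record_id, h.start, h.end))
        )
        groups_hit = frozenset(record_to_group[h.record_id] for h in hits)
        if not hits:
            classification = CLASS_UNMAPPED
        elif len(groups_hit) == 1:
            classification = CLASS_INFORMATIVE
        else:
            classification = CLASS_MULTI
        informative_cdr3 = classification == CLASS_INFORMATIVE and any(
            h.overlaps_cdr3 for h in hits
        )
        results.append(
            MappingResult(
                peptide=peptide,
                hits=hits,
                clone_groups_hit=groups_hit,
                classification=classification,
                informative_cdr3=informative_cdr3,
            )
        )
    return results


def summarize_mapping(results: list[MappingResult]) -> MappingSummary:
    """Counts per classification; informative splits into CDR3 vs other regions."""
    unmapped = sum(1 for r in results if r.classification == CLASS_UNMAPPED)
    multi = sum(1 for r in results if r.classification == CLASS_MULTI)
    informative = sum(1 for r in results if r.classification == CLASS_INFORMATIVE)
    informative_cdr3 = sum(1 for r in results if r.informative_cdr3)
    return MappingSummary(
        unmapped=unmapped,
        multi_mapped=multi,
        informative=informative,
        informative_cdr3=informative_cdr3,
        informative_other_region=informative - informative_cdr3,
    )


def informative_cdr3_groups(results: list[MappingResult]) -> set[str]:
    """Clonotype groups pinned down by informative CDR3-overlapping peptides."""
    recovered: set[str] = set()
    for result in results:
        if result.informative_cdr3:
            (group_key,) = result.clone_groups_hit
            recovered.add(group_key)
    return recovered


def write_mapping_table(results: list[MappingResult], path) -> None:
    """Write the mapping TSV: one row per peptide with its hit list."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "peptide": r.peptide,
                "classification": r.classification,
                "informative_cdr3": r.informative_cdr3,
                "n_hits": len(r.hits),
                "clone_groups_hit": ";".join(sorted(r.clone_groups_hit)),
                "hits": ";".join(
                    f"{h.record_id}:{h.start}-{h.end}:"
                    + ",".join(sorted(h.regions_overlapped))
                    for h in r.hits
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "classification",
            "informative_cdr3",
            "n_hits",
            "clone_groups_hit",
            "hits",
        ],
    ).to_csv(path, sep="\t", index=False)
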