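"""In-silico proteolytic digestion of V-region amino-acid sequences.

Cleavage follows the classical site rule: cut after any residue in
``cleave_after`` unless the next residue is in ``blocked_by_next`` (for
trypsin: after K or R, not before P). Fragments spanning up to
``max_missed_cleavages`` uncut internal sites are enumerated and filtered
to a length window; default bounds (6-40 residues, up to 2 missed
cleavages) reflect peptides observable in shotgun LC-MS/MS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

from .errors import ConfigError, ValidationError
from .repertoire import AA_ALPHABET

__all__ = ["EnzymeRule", "Fragment", "digest", "builtin_enzymes", "get_enzyme"]


@dataclass(frozen=True)
class EnzymeRule:
    """A fully specific cleavage rule plus fragment filters."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str]
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 40

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ConfigError(f"{self.name}: min_length must be >= 1")
        if self.max_length < self.min_length:
            raise ConfigError(f"{self.name}: max_length must be >= min_length")
        if self.max_missed_cleavages < 0:
            raise ConfigError(f"{self.name}: max_missed_cleavages must be >= 0")


class Fragment(NamedTuple):
    peptide: str
    start: int  # 0-based
    end: int  # exclusive
    missed: int  # uncut internal cleavage sites


def cleavage_sites(sequence: str, rule: EnzymeRule) -> list[int]:
    """Positions p (0 < p < len) such that the enzyme cuts between p-1 and p."""
    return [
        p
        for p in range(1, len(sequence))
        if sequence[p - 1] in rule.cleave_after and sequence[p] not in rule.blocked_by_next
    ]


def digest(sequence: str, rule: EnzymeRule) -> list[Fragment]:
    """Enumerate fully specific fragments with coordinates and missed-site counts.

    Output is ordered by (start, end). Residues must be in the 20-letter
    amino-acid alphabet plus X.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    for i, residue in enumerate(sequence):
        if residue not in AA_ALPHABET:
            raise ValidationError(f"invalid residue {residue!r} at position {i}")
    boundaries = [0, *cleavage_sites(sequence, rule), len(sequence)]
    fragments: list[Fragment] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + rule.max_missed_cleavages, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            if rule.min_length <= end - start <= rule.max_length:
                fragments.append(Fragment(sequence[start:end], start, end, j - i - 1))
    return fragments


def builtin_enzymes() -> dict[str, EnzymeRule]:
    """Rules for the supported proteases; trypsin is the default enzyme."""
    return {
        "trypsin": EnzymeRule(
            name="trypsin",
            cleave_after=frozenset("KR"),
            blocked_by_next=frozenset("P"),
        ),
        "lys-c": EnzymeRule(
            name="lys-c",
            cleave_after=frozenset("K"),
            blocked_by_next=frozenset(),
        ),
        "chymotrypsin": EnzymeRule(
            name="chymotrypsin",
            cleave_after=frozenset("FWY"),
            blocked_by_next=frozenset("P"),
        ),
    }


def get_enzyme(name: str, **overrides) -> EnzymeRule:
    """Look up a built-in rule by name, optionally overriding filter settings."""
    enzymes = builtin_enzymes()
    if name not in enzymes:
        raise ConfigError(
            f"unknown enzyme {name!r}; available: {', '.join(sorted(enzymes))}"
        )
    rule = enzymes[name]
    return replace(rule, **overrides) if overrides else rule
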