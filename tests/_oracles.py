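"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: digestion is checked
by validating every substring against the cleavage rule, and mapping by a
naive sliding-window scan over every clone.
"""

from __future__ import annotations


def brute_force_digest(sequence: str, cleave_after: set[str], blocked_by_next: set[str],
                       max_missed: int, min_length: int, max_length: int):
    """Enumerate (peptide, start, end, missed) by testing every substring."""

    def is_boundary(p: int) -> bool:
        if p == 0 or p == len(sequence):
            return True
        return sequence[p - 1] in cleave_after and sequence[p] not in blocked_by_next

    out = []
    for start in range(len(sequence)):
        for end in range(start + 1, len(sequence) + 1):
            if not (is_boundary(start) and is_boundary(end)):
                continue
            internal = sum(1 for p in range(start + 1, end) if is_boundary(p))
            if internal <= max_missed and min_length <= end - start <= max_length:
                out.append((sequence[start:end], start, end, internal))
    return sorted(out, key=lambda f: (f[1], f[2]))


def naive_find_all(peptide: str, text: str, fold: bool) -> list[tuple[int, int]]:
    """All (start, end) occurrences via a character-by-character window scan."""

    def f(s: str) -> str:
        return s.replace("I", "L") if fold else s

    p = f(peptide)
    t = f(text)
    hits = []
    for start in range(len(t) - len(p) + 1):
        if all(t[start + i] == p[i] for i in range(len(p))):
            hits.append((start, start + len(p)))
    return hits


def brute_force_partition(items: list, key) -> set[frozenset]:
    """Equivalence classes (as frozensets of indices) by pairwise key comparison."""
    classes: list[list[int]] = []
    for i, item in enumerate(items):
        for cls in classes:
            if key(items[cls[0]]) == key(item):
                cls.append(i)
                break
        else:
            classes.append([i])
    return {frozenset(cls) for cls in classes}
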