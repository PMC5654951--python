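"""Naive brute-force reference implementations used as independent oracles.

Everything here is deliberately simple and O(n*m): direct substring scans and
per-position counting, with no shared code with the package internals.
"""

from __future__ import annotations


def naive_placements(proteins: dict[str, str], peptide: str) -> list[tuple[str, int, int]]:
    out = []
    for pid, seq in proteins.items():
        for s in range(len(seq) - len(peptide) + 1):
            if seq[s : s + len(peptide)] == peptide:
                out.append((pid, s, s + len(peptide)))
    return sorted(out)


def naive_profile(proteins: dict[str, str], peptides: set[str], protein_id: str) -> list[int]:
    seq = proteins[protein_id]
    heights = [0] * len(seq)
    for pep in peptides:
        for (pid, s, e) in naive_placements(proteins, pep):
            if pid == protein_id:
                for i in range(s, e):
                    heights[i] += 1
    return heights


def naive_nr_matching(proteins: dict[str, str], class1: set[str], protein_id: str) -> int:
    return sum(
        1
        for pep in class1
        if any(pid == protein_id for (pid, _, _) in naive_placements(proteins, pep))
    )


def naive_match_score(
    proteins: dict[str, str], class1: set[str], wt: str
) -> tuple[int, tuple[str, int, int] | None]:
    """Max over wt placements of the summed overlap with class-I placements."""
    db_placements = [pl for pep in class1 for pl in naive_placements(proteins, pep)]
    best, best_pl = 0, None
    for (pid, s, e) in naive_placements(proteins, wt):
        total = 0
        for (qpid, qs, qe) in db_placements:
            if qpid == pid:
                total += max(0, min(e, qe) - max(s, qs))
        if best_pl is None or total > best:
            best, best_pl = total, (pid, s, e)
    return best, best_pl


def naive_classify(
    proteins: dict[str, str], class1: set[str], class2: set[str], wt: str, mutation_pos: int
) -> str:
    all_peps = class1 | class2
    if wt in all_peps:
        return "exact"
    if any(len(p) > len(wt) and wt in p for p in all_peps):
        return "included"
    db_placements = [pl for pep in all_peps for pl in naive_placements(proteins, pep)]
    for (pid, s, _e) in naive_placements(proteins, wt):
        pos = s + mutation_pos
        for (qpid, qs, qe) in db_placements:
            if qpid == pid and qs <= pos < qe:
                return "partial"
    return "none"


def naive_hotspot_runs(heights: list[int], threshold: int, merge_gap: int) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(heights):
        if heights[i] >= threshold:
            j = i
            while j < len(heights) and heights[j] >= threshold:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for (s, e) in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
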