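"""Per-residue presentation density profiles and antigen-presentation hotspots.

A density profile counts, for each residue of a protein, how many unique
HLA-peptide placements of a class selector (I, II, I/II shared, or class-I
shorter than 15-mers) cover that residue.  Hotspots are maximal runs of the
profile above a threshold, optionally merged across short gaps.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .peptidome_db import (
    HLA2_EXPRESSION_THRESHOLD,
    PeptidomeDB,
)


@dataclass(frozen=True)
class DensityProfile:
    """Coverage heights for one protein and one class selector.

    ``heights[i]`` is the number of peptide placements of the selector that
    cover residue ``i``; ``sum(heights)`` therefore equals the summed lengths
    of all contributing placements.
    """

    protein_id: str
    class_selector: str
    heights: np.ndarray
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "heights", np.asarray(self.heights, dtype=np.int64))
        if len(self.heights) != len(self.sequence):
            raise ValueError(
                f"profile length {len(self.heights)} != protein length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class Hotspot:
    """A maximal above-threshold interval of a density profile (half-open)."""

    protein_id: str
    start: int
    end: int
    peak_height: int
    area: int


def density_profile(db: PeptidomeDB, protein_id: str, class_selector: str) -> DensityProfile:
    """Per-residue coverage of one protein by unique peptides of a selector.

    Each placement contributes once; a peptide placed twice in the protein
    contributes at both placements.  Profiles are cached on the database.
    """
    if protein_id not in db.proteins:
        raise KeyError(f"unknown protein {protein_id!r}")
    cache_key = (protein_id, class_selector)
    cached = db._profile_cache.get(cache_key)
    if cached is not None:
        return cached

    selected = db.peptides_for_selector(class_selector)
    seq = db.proteins[protein_id].sequence
    heights = np.zeros(len(seq), dtype=np.int64)
    for (pep, start, end) in db.placements_by_protein.get(protein_id, ()):
        if pep in selected:
            heights[start:end] += 1
    profile = DensityProfile(protein_id, class_selector, heights, seq)
    db._profile_cache[cache_key] = profile
    return profile


def segment_hotspots(
    profile: DensityProfile,
    min_height: int = 2,
    min_frac_of_max: float = 0.0,
    merge_gap: int = 0,
) -> list[Hotspot]:
    """Threshold-and-merge hotspot segmentation.

    The threshold is ``max(min_height, ceil(min_frac_of_max * max(heights)))``.
    Maximal runs of positions with height >= threshold are reported; runs
    separated by fewer than ``merge_gap`` positions are merged.  An all-zero
    profile yields no hotspots.
    """
    if min_height < 0 or min_frac_of_max < 0 or merge_gap < 0:
        raise ValueError("segment_hotspots parameters must be non-negative")
    heights = profile.heights
    if heights.size == 0 or int(heights.max()) == 0:
        return []
    threshold = max(min_height, math.ceil(min_frac_of_max * int(heights.max())))
    threshold = max(threshold, 1)

    above = heights >= threshold
    runs: list[list[int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    if not runs:
        return []

    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] < merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    return [
        Hotspot(
            protein_id=profile.protein_id,
            start=s,
            end=e,
            peak_height=int(heights[s:e].max()),
            area=int(heights[s:e].sum()),
        )
        for s, e in merged
    ]


def main_peak_correlation(
    profile_a: DensityProfile, profile_b: DensityProfile, peak_frac: float = 0.5
) -> float:
    """Similarity of two profiles via overlap of their main peaks.

    Each profile is binarized at ``peak_frac`` of its own maximum (so small
    peaks are ignored) and the Jaccard index of the two masks is returned.
    0.0 when either mask is empty.
    """
    a, b = profile_a.heights, profile_b.heights
    if len(a) != len(b):
        raise ValueError("profiles must be over the same protein (equal lengths)")
    mask_a = a >= max(peak_frac * a.max(), 1) if a.max() > 0 else np.zeros_like(a, bool)
    mask_b = b >= max(peak_frac * b.max(), 1) if b.max() > 0 else np.zeros_like(b, bool)
    union = int(np.logical_or(mask_a, mask_b).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(mask_a, mask_b).sum())
    return inter / union


def _intersects(h: Hotspot, others: list[Hotspot]) -> bool:
    return any(h.start < o.end and o.start < h.end for o in others)


def hotspot_overlap_stats(
    db: PeptidomeDB,
    min_height: int = 2,
    min_frac_of_max: float = 0.0,
    merge_gap: int = 0,
) -> dict:
    """Overlap of shared (I/II) hotspots with class-II versus class-I hotspots.

    For each protein carrying at least one I/II hotspot, reports the fraction
    of its I/II hotspots whose interval intersects a class-II hotspot, and
    likewise for class-I; plus database-wide mean fractions and a paired
    Wilcoxon signed-rank p-value across proteins.
    """
    rows = []
    kw = dict(min_height=min_height, min_frac_of_max=min_frac_of_max, merge_gap=merge_gap)
    for pid in db.proteins:
        shared_hs = segment_hotspots(density_profile(db, pid, "I/II"), **kw)
        if not shared_hs:
            continue
        hs1 = segment_hotspots(density_profile(db, pid, "I"), **kw)
        hs2 = segment_hotspots(density_profile(db, pid, "II"), **kw)
        frac_ii = sum(_intersects(h, hs2) for h in shared_hs) / len(shared_hs)
        frac_i = sum(_intersects(h, hs1) for h in shared_hs) / len(shared_hs)
        rows.append((pid, len(shared_hs), frac_ii, frac_i))

    table = pd.DataFrame(
        rows, columns=["protein_id", "n_shared_hotspots", "overlap_frac_II", "overlap_frac_I"]
    )
    if table.empty:
        return {"per_protein": table, "mean_overlap_II": None, "mean_overlap_I": None, "wilcoxon_p": None}

    diffs = table["overlap_frac_II"] - table["overlap_frac_I"]
    if (diffs == 0).all() or len(table) < 2:
        p = 1.0
    else:
        p = float(stats.wilcoxon(table["overlap_frac_II"], table["overlap_frac_I"]).pvalue)
    return {
        "per_protein": table,
        "mean_overlap_II": float(table["overlap_frac_II"].mean()),
        "mean_overlap_I": float(table["overlap_frac_I"].mean()),
        "wilcoxon_p": p,
    }


@dataclass(frozen=True)
class LengthDistribution:
    class_selector: str
    counts: dict[int, int]
    modal_length: int | None


def length_distribution(db: PeptidomeDB, class_selector: str) -> LengthDistribution:
    """Histogram of unique peptide lengths for a class selector, with mode."""
    counter = Counter(len(p) for p in db.peptides_for_selector(class_selector))
    counts = dict(sorted(counter.items()))
    mode = max(counts, key=lambda k: (counts[k], -k)) if counts else None
    return LengthDistribution(class_selector, counts, mode)


def long_peptide_proportion(db: PeptidomeDB, min_len: int = 14) -> dict:
    """Per-sample proportion of long unique class-I peptides, by HLA-II status.

    For every sample, the proportion of its unique class-I peptides of length
    >= ``min_len`` is computed; samples are grouped by whether they express
    HLA-II (>= 100 HLA-II peptides detected), and group means/SDs and the
    descriptive difference are reported.  A group with no samples has missing
    (None) statistics.
    """
    rows = []
    for sid, meta in db.samples.items():
        peps = {o.sequence for o in db.observations_by_sample.get(sid, ()) if o.hla_class == "I"}
        if not peps:
            continue
        prop = sum(len(p) >= min_len for p in peps) / len(peps)
        rows.append((sid, meta.group, meta.hla2_expressing, len(peps), prop))
    per_sample = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "hla2_expressing", "n_class1_peptides", "long_proportion"],
    )

    def _grp(expressing: bool) -> dict:
        sub = per_sample[per_sample["hla2_expressing"] == expressing]["long_proportion"]
        if sub.empty:
            return {"n": 0, "mean": None, "sd": None}
        return {
            "n": int(len(sub)),
            "mean": float(sub.mean()),
            "sd": float(sub.std(ddof=1)) if len(sub) > 1 else 0.0,
        }

    expressing, lacking = _grp(True), _grp(False)
    diff = (
        expressing["mean"] - lacking["mean"]
        if expressing["mean"] is not None and lacking["mean"] is not None
        else None
    )
    return {
        "per_sample": per_sample,
        "min_len": min_len,
        "hla2_expressing": expressing,
        "hla2_lacking": lacking,
        "mean_difference": diff,
        "hla2_threshold": HLA2_EXPRESSION_THRESHOLD,
    }


# -------------------------------------------------------------------- export
def export_profile(
    profile: DensityProfile,
    path: str | Path,
    format: str = "tsv",
    skip_zero: bool = False,
) -> Path:
    """Write a profile as TSV (position, residue, height; 1-based) or bedGraph.

    bedGraph treats the protein as its own reference sequence (protein_id in
    the chromosome field, 0-based half-open intervals) with runs of equal
    height merged; with ``skip_zero`` zero-height runs are omitted.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            {
                "position": np.arange(1, len(profile.heights) + 1),
                "residue": list(profile.sequence),
                "height": profile.heights,
            }
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "bedgraph":
        lines = []
        h = profile.heights
        i = 0
        while i < len(h):
            j = i
            while j < len(h) and h[j] == h[i]:
                j += 1
            if not (skip_zero and h[i] == 0):
                lines.append(f"{profile.protein_id}\t{i}\t{j}\t{int(h[i])}")
            i = j
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown export format {format!r}; expected 'tsv' or 'bedgraph'")
    return path


def read_profile_tsv(path: str | Path, protein_id: str, class_selector: str) -> DensityProfile:
    """Re-parse a TSV profile written by :func:`export_profile`."""
    df = pd.read_csv(path, sep="\t")
    return DensityProfile(
        protein_id=protein_id,
        class_selector=class_selector,
        heights=df["height"].to_numpy(),
        sequence="".join(df["residue"].astype(str)),
    )
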