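"""Self-contained synthetic fixtures for the whole pipeline.

Emulates the statistical structure of a large immunopeptidomics resource:
class-I peptides of mostly 9-11 residues, class-II peptides of mainly 13-17
residues centered on 15-mers, a small fraction of sequences shared between
the classes, non-uniform per-protein peptide counts with planted
presentation hotspots, and a Stronen-style neoantigen candidate table
(~1,000 candidates, ~16 immunogenic) whose labels correlate with the
binding/stability/expression features and with database match status.

Every generator records a truth manifest (planted hotspot intervals, match
type counts, labels, per-class counts) so downstream recovery tests are
self-verifying.  Identical spec + seed reproduce outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .peptidome_db import (
    PeptidomeDB,
    PeptideObservation,
    ProteinRecord,
    SampleMeta,
    build_db,
    write_proteome,
)
from .neoantigen_scoring import classify_match, find_placements

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# class-I length mass, mode 9; P(>=14) = 0.048 matches the observed share of
# long class-I peptides in samples lacking HLA-II expression
DEFAULT_CLASS1_LENGTHS = {8: 0.03, 9: 0.422, 10: 0.27, 11: 0.14, 12: 0.06, 13: 0.03, 14: 0.048}
# class-II length mass, centered on 15-mers
DEFAULT_CLASS2_LENGTHS = {12: 0.05, 13: 0.10, 14: 0.17, 15: 0.26, 16: 0.18, 17: 0.12, 18: 0.07, 19: 0.03, 20: 0.02}


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic study, with desk-scale defaults.

    The candidate block mirrors the Stronen et al. screen dimensions: 1,034
    candidates, 16 immunogenic, 872 on database proteins.
    """

    seed: int
    # proteome
    n_proteins: int = 80
    protein_length: tuple[int, int] = (200, 600)
    # samples: (group, n_samples, class-I yield, class-II yield); groups with
    # zero class-II yield model HLA-II non-expressing samples
    sample_plan: tuple = (
        ("B-cells", 3, 400, 250),
        ("T-cells", 2, 300, 200),
        ("Melanoma", 3, 350, 150),
        ("other", 2, 300, 0),
    )
    class1_length_dist: dict = field(default_factory=lambda: dict(DEFAULT_CLASS1_LENGTHS))
    class2_length_dist: dict = field(default_factory=lambda: dict(DEFAULT_CLASS2_LENGTHS))
    shared_fraction: float = 0.034
    # extra long-peptide mass for HLA-II-expressing samples (5.6% vs 4.8%)
    long_peptide_boost: float = 0.008
    # background pools (global, placements kept non-overlapping per class so
    # background coverage stays <= 1 and planted hotspots stand out)
    class1_pool_size: int = 1300
    class1_pool_long_fraction: float = 0.10
    class2_pool_size: int = 550
    # class-I hotspots planted for recovery tests
    n_hotspots: int = 12
    hotspot_length: int = 25
    hotspot_depth: int = 6
    # shared (I/II) hotspots and their planted overlap structure
    n_shared_hotspots: int = 10
    shared_hotspot_depth: int = 2
    decoy_hotspot_depth: int = 8
    p_overlap_ii: float = 0.7
    p_overlap_i: float = 0.3
    # candidates
    n_candidates: int = 1034
    n_immunogenic: int = 16
    match_mix: dict = field(
        default_factory=lambda: {"exact": 7, "included": 12, "partial": 47, "none": 968}
    )
    immunogenic_match_mix: dict = field(
        default_factory=lambda: {"exact": 2, "included": 3, "partial": 5, "none": 6}
    )
    n_on_db_proteins: int = 872
    # feature effect sizes (log-scale shifts for immunogenic candidates)
    affinity_mu_control: float = 8.0
    affinity_mu_immuno: float = 6.8
    affinity_sigma: float = 1.3
    wt_affinity_shift_immuno: float = 0.8
    stability_shift_immuno: float = 0.7
    rna_shift_immuno: float = 0.7
    ms_feature_signal: bool = True  # kept for clarity; the mix fields carry it

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("GeneratorSpec.seed is mandatory")
        for dist in (self.class1_length_dist, self.class2_length_dist):
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"length distribution does not sum to 1 (got {total})")
        if sum(self.match_mix.values()) != self.n_candidates:
            raise ValueError("match_mix must sum to n_candidates")
        if sum(self.immunogenic_match_mix.values()) != self.n_immunogenic:
            raise ValueError("immunogenic_match_mix must sum to n_immunogenic")
        for t, k in self.immunogenic_match_mix.items():
            if k > self.match_mix.get(t, 0):
                raise ValueError(f"more immunogenic than total candidates of type {t!r}")


def _draw_lengths(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    lengths = np.array(sorted(dist))
    probs = np.array([dist[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(lengths, size=n, p=probs)


# ------------------------------------------------------------------ proteome
def generate_proteome(spec: GeneratorSpec) -> tuple[list[ProteinRecord], dict]:
    """Random proteome with i.i.d. residues (uniform background composition)."""
    rng = np.random.default_rng([spec.seed, 1])
    lo, hi = spec.protein_length
    lengths = rng.integers(lo, hi + 1, size=spec.n_proteins)
    records = []
    for i, length in enumerate(lengths):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=int(length)))
        records.append(ProteinRecord(f"SYN{i:04d}", seq))
    manifest = {
        "seed": spec.seed,
        "n_proteins": spec.n_proteins,
        "protein_lengths": {r.protein_id: len(r.sequence) for r in records},
    }
    return records, manifest


# ----------------------------------------------------------------- peptidome
def _plant_windows(
    rng: np.random.Generator,
    sequence: str,
    start: int,
    end: int,
    depth: int,
    window_lengths: tuple[int, ...],
) -> list[tuple[str, int, int]]:
    """Staggered overlapping windows until every position of [start, end) is
    covered by at least ``depth`` distinct windows.

    Windows fully inside the interval are used first (triangular shoulders
    stay inside); when the interval edges cannot reach the target depth with
    inside windows alone, windows overhanging the boundary are added with the
    smallest overhang first, so coverage spills only a few residues beyond
    the planted interval.
    """
    candidates = []
    for L in window_lengths:
        for s in range(max(0, start - L + 1), min(len(sequence) - L, end - 1) + 1):
            candidates.append((s, s + L))
    if not any(s >= start and e <= end for (s, e) in candidates):
        raise ValueError("hotspot interval shorter than the smallest window length")
    # random priority for tie-breaking; greedy selection keeps the profile
    # near-rectangular at the target depth instead of piling up in the center
    priority = {w: i for i, w in zip(rng.permutation(len(candidates)), candidates)}

    coverage = np.zeros(end - start, dtype=int)
    available = set(candidates)
    chosen: list[tuple[str, int, int]] = []
    while coverage.min() < depth:
        p = start + int(np.argmin(coverage))
        covering = [w for w in available if w[0] <= p < w[1]]
        if not covering:
            raise ValueError("hotspot interval cannot reach the requested coverage depth")

        def _cost(w: tuple[int, int]) -> tuple[int, int, int]:
            lo, hi = max(w[0], start), min(w[1], end)
            excess = int((coverage[lo - start : hi - start] >= depth).sum())
            spill = max(start - w[0], 0) + max(w[1] - end, 0)
            return (spill, excess, priority[w])

        s, e = min(covering, key=_cost)
        available.remove((s, e))
        chosen.append((sequence[s:e], s, e))
        lo, hi = max(s, start), min(e, end)
        coverage[lo - start : hi - start] += 1
    return chosen


def _disjoint_interval(
    rng: np.random.Generator,
    length: int,
    protein_len: int,
    occupied: list[tuple[int, int]],
    margin: int = 20,
) -> tuple[int, int]:
    """Interval placed at least ``margin`` residues from protein ends and
    from other planted intervals, so coverage shoulders never bridge them."""
    if protein_len < length + 2 * margin:
        raise ValueError("protein too short for a planted hotspot interval")
    for _ in range(500):
        s = int(rng.integers(margin, protein_len - length - margin + 1))
        e = s + length
        if all(e + margin <= os or oe + margin <= s for (os, oe) in occupied):
            return s, e
    raise ValueError("could not place a disjoint hotspot interval")


def generate_peptidome(
    spec: GeneratorSpec, proteome: list[ProteinRecord]
) -> tuple[list[PeptideObservation], list[SampleMeta], dict]:
    """Peptide observations with planted hotspots and background coverage <= 1.

    Class-I hotspots (for recovery tests) are planted on the first
    ``n_hotspots`` proteins; shared (I/II) hotspots on the next
    ``n_shared_hotspots`` proteins.  At a shared hotspot the shared peptides
    themselves give both class profiles a moderate peak; with probability
    ``1 - p_overlap_ii`` (resp. ``1 - p_overlap_i``) a deep class-II-only
    (resp. class-I-only) decoy hotspot is planted elsewhere on the protein so
    that, under a relative segmentation threshold, the shared interval no
    longer qualifies as a class-II (resp. class-I) hotspot.  Background
    peptides are globally non-overlapping within each class.
    """
    if spec.n_hotspots + spec.n_shared_hotspots > spec.n_proteins:
        raise ValueError("not enough proteins for the requested hotspot plan")
    rng = np.random.default_rng([spec.seed, 2])
    prot_list = list(proteome)
    prot_seq = {p.protein_id: p.sequence for p in prot_list}

    # occupancy masks guaranteeing background coverage <= 1 per class
    mask1 = {p.protein_id: np.zeros(len(p.sequence), dtype=bool) for p in prot_list}
    mask2 = {p.protein_id: np.zeros(len(p.sequence), dtype=bool) for p in prot_list}

    class1_hotspot_peps: list[tuple[str, str]] = []  # (sequence, protein_id)
    class2_hotspot_peps: list[tuple[str, str]] = []
    shared_hotspot_peps: list[tuple[str, str]] = []
    planted_class1_hotspots: list[dict] = []
    planted_shared_hotspots: list[dict] = []

    # --- class-I recovery hotspots
    for i in range(spec.n_hotspots):
        prot = prot_list[i]
        L = len(prot.sequence)
        if spec.hotspot_length + 20 > L:
            raise ValueError(f"hotspot longer than protein {prot.protein_id}")
        s = int(rng.integers(10, L - spec.hotspot_length - 10))
        e = s + spec.hotspot_length
        windows = _plant_windows(rng, prot.sequence, s, e, spec.hotspot_depth, (9, 10, 11))
        for (seq, ws, we) in windows:
            class1_hotspot_peps.append((seq, prot.protein_id))
            mask1[prot.protein_id][ws:we] = True
        planted_class1_hotspots.append(
            {"protein_id": prot.protein_id, "start": s, "end": e, "depth": spec.hotspot_depth}
        )

    # --- shared hotspots with planted overlap structure
    for j in range(spec.n_shared_hotspots):
        prot = prot_list[spec.n_hotspots + j]
        L = len(prot.sequence)
        occupied: list[tuple[int, int]] = []
        a_s, a_e = _disjoint_interval(rng, spec.hotspot_length, L, occupied)
        occupied.append((a_s, a_e))
        windows = _plant_windows(
            rng, prot.sequence, a_s, a_e, spec.shared_hotspot_depth, (12, 13, 14, 15, 16)
        )
        for (seq, ws, we) in windows:
            shared_hotspot_peps.append((seq, prot.protein_id))
            mask1[prot.protein_id][ws:we] = True
            mask2[prot.protein_id][ws:we] = True

        overlap_ii = bool(rng.random() < spec.p_overlap_ii)
        overlap_i = bool(rng.random() < spec.p_overlap_i)
        decoys = {}
        if not overlap_ii:
            b_s, b_e = _disjoint_interval(rng, spec.hotspot_length, L, occupied)
            occupied.append((b_s, b_e))
            for (seq, ws, we) in _plant_windows(
                rng, prot.sequence, b_s, b_e, spec.decoy_hotspot_depth, (13, 14, 15, 16, 17)
            ):
                class2_hotspot_peps.append((seq, prot.protein_id))
                mask2[prot.protein_id][ws:we] = True
            decoys["class2_decoy"] = {"start": b_s, "end": b_e}
        if not overlap_i:
            c_s, c_e = _disjoint_interval(rng, spec.hotspot_length, L, occupied)
            occupied.append((c_s, c_e))
            for (seq, ws, we) in _plant_windows(
                rng, prot.sequence, c_s, c_e, spec.decoy_hotspot_depth, (9, 10, 11)
            ):
                class1_hotspot_peps.append((seq, prot.protein_id))
                mask1[prot.protein_id][ws:we] = True
            decoys["class1_decoy"] = {"start": c_s, "end": c_e}
        planted_shared_hotspots.append(
            {
                "protein_id": prot.protein_id,
                "start": a_s,
                "end": a_e,
                "depth": spec.shared_hotspot_depth,
                "overlap_ii": overlap_ii,
                "overlap_i": overlap_i,
                **decoys,
            }
        )

    # --- background pools: globally non-overlapping placements per class
    prot_ids = [p.protein_id for p in prot_list]
    prot_weights = np.array([len(p.sequence) for p in prot_list], dtype=float)
    prot_weights /= prot_weights.sum()

    def _fill_pool(mask: dict, lengths: np.ndarray) -> dict[str, tuple[str, int, int]]:
        pool: dict[str, tuple[str, int, int]] = {}
        attempts = 0
        i = 0
        while i < len(lengths) and attempts < 60 * len(lengths):
            attempts += 1
            pid = rng.choice(prot_ids, p=prot_weights)
            seq = prot_seq[pid]
            L = int(lengths[i])
            if len(seq) <= L:
                continue
            s = int(rng.integers(0, len(seq) - L + 1))
            if mask[pid][s : s + L].any():
                continue
            pep = seq[s : s + L]
            if pep in pool:
                continue
            mask[pid][s : s + L] = True
            pool[pep] = (pid, s, s + L)
            i += 1
        return pool

    n1 = spec.class1_pool_size
    n_long = int(round(n1 * spec.class1_pool_long_fraction))
    short_dist = {k: v for k, v in spec.class1_length_dist.items() if k < 14}
    long_dist = {k: v for k, v in spec.class1_length_dist.items() if k >= 14}
    if not long_dist:
        long_dist = {14: 1.0}
    lengths1 = np.concatenate(
        [_draw_lengths(rng, short_dist, n1 - n_long), _draw_lengths(rng, long_dist, n_long)]
    )
    pool1 = _fill_pool(mask1, lengths1)
    pool1_short = [p for p in pool1 if len(p) < 14]
    pool1_long = [p for p in pool1 if len(p) >= 14]
    pool2_map = _fill_pool(mask2, _draw_lengths(rng, spec.class2_length_dist, spec.class2_pool_size))
    pool2 = list(pool2_map)

    # --- samples and per-sample draws
    samples: list[SampleMeta] = []
    observations: list[PeptideObservation] = []
    sample_yields: list[tuple[str, int, int]] = []
    k = 0
    for (group, n_samples, y1, y2) in spec.sample_plan:
        for _ in range(n_samples):
            sid = f"S{k:02d}_{group}"
            sample_yields.append((sid, y1, y2))
            samples.append(SampleMeta(sid, group, 0))  # class-II count patched below
            k += 1

    p_long_base = sum(v for l, v in spec.class1_length_dist.items() if l >= 14)
    class2_counts: dict[str, int] = {s.sample_id: 0 for s in samples}

    for (sid, y1, y2) in sample_yields:
        expressing = y2 >= 100
        p_long = p_long_base + (spec.long_peptide_boost if expressing else 0.0)
        n_long_s = min(int(rng.binomial(y1, p_long)), len(pool1_long))
        n_short_s = min(y1 - n_long_s, len(pool1_short))
        for pep in rng.choice(pool1_long, size=n_long_s, replace=False):
            observations.append(PeptideObservation(str(pep), sid, "I"))
        for pep in rng.choice(pool1_short, size=n_short_s, replace=False):
            observations.append(PeptideObservation(str(pep), sid, "I"))
        if y2 > 0:
            n2 = min(y2, len(pool2))
            for pep in rng.choice(pool2, size=n2, replace=False):
                observations.append(PeptideObservation(str(pep), sid, "II"))
            class2_counts[sid] += n2

    class1_sample_ids = [s for (s, y1, _) in sample_yields if y1 > 0]
    class2_sample_ids = [s for (s, _, y2) in sample_yields if y2 >= 100]
    if not class2_sample_ids:
        class2_sample_ids = class1_sample_ids

    for (pep, _pid) in class1_hotspot_peps:
        observations.append(
            PeptideObservation(pep, str(rng.choice(class1_sample_ids)), "I")
        )
    for (pep, _pid) in class2_hotspot_peps:
        sid = str(rng.choice(class2_sample_ids))
        observations.append(PeptideObservation(pep, sid, "II"))
        class2_counts[sid] += 1
    for (pep, _pid) in shared_hotspot_peps:
        observations.append(
            PeptideObservation(pep, str(rng.choice(class1_sample_ids)), "I")
        )
        sid = str(rng.choice(class2_sample_ids))
        observations.append(PeptideObservation(pep, sid, "II"))
        class2_counts[sid] += 1

    # --- top up sharing to the target fraction by re-emitting class-I
    # background peptides in class-II samples
    class1_unique = {o.sequence for o in observations if o.hla_class == "I"}
    class2_unique = {o.sequence for o in observations if o.hla_class == "II"}
    n_shared_now = len(class1_unique & class2_unique)
    target_shared = int(round(spec.shared_fraction * len(class1_unique)))
    reemitted = 0
    if target_shared > n_shared_now:
        # only background class-I peptides whose placement is still free in
        # the class-II mask, so class-II background coverage stays <= 1
        eligible = sorted(
            pep
            for pep in class1_unique - class2_unique
            if pep in pool1 and not mask2[pool1[pep][0]][pool1[pep][1] : pool1[pep][2]].any()
        )
        n_extra = min(target_shared - n_shared_now, len(eligible))
        for pep in rng.choice(eligible, size=n_extra, replace=False):
            pep = str(pep)
            sid = str(rng.choice(class2_sample_ids))
            observations.append(PeptideObservation(pep, sid, "II"))
            pid, s, e = pool1[pep]
            mask2[pid][s:e] = True
            class2_counts[sid] += 1
            reemitted += 1

    samples = [
        SampleMeta(s.sample_id, s.group, class2_counts[s.sample_id]) for s in samples
    ]

    class1_unique = {o.sequence for o in observations if o.hla_class == "I"}
    class2_unique = {o.sequence for o in observations if o.hla_class == "II"}
    n_over = len(planted_shared_hotspots)
    manifest = {
        "seed": spec.seed,
        "n_observations": len(observations),
        "n_class1_observations": sum(o.hla_class == "I" for o in observations),
        "n_class2_observations": sum(o.hla_class == "II" for o in observations),
        "n_class1_unique": len(class1_unique),
        "n_class2_unique": len(class2_unique),
        "n_shared_unique": len(class1_unique & class2_unique),
        "n_reemitted_shared": reemitted,
        "class1_hotspots": planted_class1_hotspots,
        "shared_hotspots": planted_shared_hotspots,
        "realized_overlap_ii": (
            sum(h["overlap_ii"] for h in planted_shared_hotspots) / n_over if n_over else None
        ),
        "realized_overlap_i": (
            sum(h["overlap_i"] for h in planted_shared_hotspots) / n_over if n_over else None
        ),
    }
    return observations, samples, manifest


# ---------------------------------------------------------------- candidates
def _mutate(rng: np.random.Generator, wt: str, pos: int) -> str:
    alternatives = [a for a in AMINO_ACIDS if a != wt[pos]]
    return wt[:pos] + str(rng.choice(alternatives)) + wt[pos + 1 :]


def generate_candidates(
    spec: GeneratorSpec, proteome: list[ProteinRecord], db: PeptidomeDB
) -> tuple[pd.DataFrame, dict]:
    """Neoantigen candidate table with a controlled match-type mix.

    Wild-type peptides are drawn so that the database match classification
    (exact / included / partial / none) hits the planted counts exactly
    (verified during generation); immunogenic labels are concentrated in the
    matched classes and immunogenic candidates receive planted shifts on the
    affinity, stability and expression features.
    """
    rng = np.random.default_rng([spec.seed, 3])
    prot_list = [p for p in proteome if p.protein_id in db.proteins]
    all_db_peps = db.class1_peptides | db.class2_peptides

    # coverage-by-any-db-peptide mask, for placing unmatched candidates
    covered = {p.protein_id: np.zeros(len(p.sequence), dtype=bool) for p in prot_list}
    for pid, placements in db.placements_by_protein.items():
        for (_pep, s, e) in placements:
            covered[pid][s:e] = True

    class1_mapped = sorted(
        pep
        for pep in db.class1_peptides
        if db.occurrence_index.get(pep) and 9 <= len(pep) <= 11
    )
    long_db_peps = sorted(p for p in all_db_peps if len(p) >= 12 and db.occurrence_index.get(p))
    class1_placements = sorted(
        (pep, pid, s, e)
        for pep in db.class1_peptides
        for (pid, s, e) in db.occurrence_index.get(pep, ())
    )

    def _gen_exact(used: set[str]) -> tuple[str, str, int] | None:
        for _ in range(200):
            pep = str(rng.choice(class1_mapped))
            if pep in used:
                continue
            pos = int(rng.integers(0, len(pep)))
            return pep, db.occurrence_index[pep][0][0], pos
        return None

    def _gen_included(used: set[str]) -> tuple[str, str, int] | None:
        for _ in range(500):
            host = str(rng.choice(long_db_peps))
            L = int(rng.integers(9, 12))
            if len(host) <= L:
                continue
            off = int(rng.integers(0, len(host) - L + 1))
            wt = host[off : off + L]
            if wt in used or wt in all_db_peps:
                continue
            pos = int(rng.integers(0, L))
            if classify_match(db, wt, pos) != "included":
                continue
            pid = db.occurrence_index[host][0][0]
            return wt, pid, pos
        return None

    def _gen_partial(used: set[str]) -> tuple[str, str, int] | None:
        for _ in range(500):
            (pep, pid, s, e) = class1_placements[int(rng.integers(len(class1_placements)))]
            seq = db.proteins[pid].sequence
            L = int(rng.integers(9, 12))
            lo = max(0, s - L + 1)
            hi = min(len(seq) - L, e - 1)
            if hi < lo:
                continue
            w_s = int(rng.integers(lo, hi + 1))
            wt = seq[w_s : w_s + L]
            mut_lo = max(s, w_s) - w_s
            mut_hi = min(e, w_s + L) - w_s
            if mut_hi <= mut_lo:
                continue
            pos = int(rng.integers(mut_lo, mut_hi))
            if wt in used or classify_match(db, wt, pos) != "partial":
                continue
            return wt, pid, pos
        return None

    def _gen_none_ondb(used: set[str]) -> tuple[str, str, int] | None:
        for _ in range(2000):
            prot = prot_list[int(rng.integers(len(prot_list)))]
            seq = prot.sequence
            L = int(rng.integers(9, 12))
            if len(seq) <= L:
                continue
            w_s = int(rng.integers(0, len(seq) - L + 1))
            pos = int(rng.integers(0, L))
            if covered[prot.protein_id][w_s + pos]:
                continue
            wt = seq[w_s : w_s + L]
            if wt in used or classify_match(db, wt, pos) != "none":
                continue
            return wt, prot.protein_id, pos
        return None

    def _gen_none_offdb(used: set[str], idx: int) -> tuple[str, str, int] | None:
        for _ in range(200):
            L = int(rng.integers(9, 12))
            wt = "".join(rng.choice(list(AMINO_ACIDS), size=L))
            if wt in used or find_placements(db, wt):
                continue
            pos = int(rng.integers(0, L))
            return wt, f"OFFDB{idx:04d}", pos
        return None

    n_off_db = spec.n_candidates - spec.n_on_db_proteins
    n_none_ondb = spec.match_mix["none"] - n_off_db
    if n_none_ondb < 0:
        raise ValueError("n_on_db_proteins inconsistent with match_mix['none']")

    plan: list[tuple[str, bool]] = []  # (generator kind, on_db)
    plan += [("exact", True)] * spec.match_mix["exact"]
    plan += [("included", True)] * spec.match_mix["included"]
    plan += [("partial", True)] * spec.match_mix["partial"]
    plan += [("none_ondb", True)] * n_none_ondb
    plan += [("none_offdb", False)] * n_off_db

    used: set[str] = set()
    rows = []
    off_idx = 0
    for kind, _on_db in plan:
        if kind == "exact":
            res = _gen_exact(used)
        elif kind == "included":
            res = _gen_included(used)
        elif kind == "partial":
            res = _gen_partial(used)
        elif kind == "none_ondb":
            res = _gen_none_ondb(used)
        else:
            res = _gen_none_offdb(used, off_idx)
            off_idx += 1
        if res is None:
            raise ValueError(f"could not generate a candidate of kind {kind!r}")
        wt, pid, pos = res
        used.add(wt)
        mut = _mutate(rng, wt, pos)
        match_type = "none" if kind.startswith("none") else kind
        rows.append(
            {
                "mut_peptide": mut,
                "wt_peptide": wt,
                "mutation_pos": pos,
                "protein_id": pid,
                "planted_match": match_type,
            }
        )

    # immunogenic labels concentrated in matched classes
    df = pd.DataFrame(rows)
    df["immunogenic"] = False
    for mtype, k in spec.immunogenic_match_mix.items():
        idx = df.index[df["planted_match"] == mtype]
        if mtype == "none":  # immunogenic unmatched candidates stay on db proteins
            idx = df.index[(df["planted_match"] == "none") & ~df["protein_id"].str.startswith("OFFDB")]
        chosen = rng.choice(idx.to_numpy(), size=k, replace=False)
        df.loc[chosen, "immunogenic"] = True

    # shuffle and assign ids in output order
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "candidate_id", [f"cand_{i:04d}" for i in range(len(df))])

    # features: log-scale shifts for immunogenic candidates
    n = len(df)
    immuno = df["immunogenic"].to_numpy()
    mu_aff = np.where(immuno, spec.affinity_mu_immuno, spec.affinity_mu_control)
    mutAffinity = np.exp(rng.normal(mu_aff, spec.affinity_sigma))
    wtAffinity = mutAffinity * np.exp(
        rng.normal(np.where(immuno, spec.wt_affinity_shift_immuno, 0.0), 0.6)
    )
    mutStab = np.exp(rng.normal(np.where(immuno, spec.stability_shift_immuno, 0.0), 0.8))
    wtStab = mutStab * np.exp(rng.normal(np.where(immuno, -0.5, 0.0), 0.5))
    df["mutAffinity"] = mutAffinity
    df["wtAffinity"] = wtAffinity
    df["mutPeptideStability"] = mutStab
    df["wtPeptideStability"] = wtStab
    df["mutCleavProb"] = rng.beta(2.0, 2.0, size=n)
    df["wtCleavProb"] = rng.beta(2.0, 2.0, size=n)
    df["mutReads"] = rng.poisson(np.exp(rng.normal(3.0, 1.0, size=n)))
    df["wtReads"] = rng.poisson(np.exp(rng.normal(3.5, 1.0, size=n)))
    df["rnaExpr"] = np.exp(rng.normal(np.where(immuno, 2.0 + spec.rna_shift_immuno, 2.0), 1.5))

    manifest = {
        "seed": spec.seed,
        "n_candidates": n,
        "n_immunogenic": int(df["immunogenic"].sum()),
        "planted_match_counts": df["planted_match"].value_counts().to_dict(),
        "planted_immunogenic_match_counts": df.loc[df["immunogenic"], "planted_match"]
        .value_counts()
        .to_dict(),
        "n_on_db_proteins": int((~df["protein_id"].str.startswith("OFFDB")).sum()),
        "immunogenic_ids": sorted(df.loc[df["immunogenic"], "candidate_id"]),
    }
    return df, manifest


# ------------------------------------------------------------------ pipeline
def simulate(spec: GeneratorSpec, out_dir: str | Path) -> dict:
    """Generate and write a complete fixture set; returns the truth manifest.

    Writes proteome.fasta, peptides.tsv, samples.tsv, candidates.tsv and
    truth.json in the formats the loader functions read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteome, prot_manifest = generate_proteome(spec)
    observations, samples, pep_manifest = generate_peptidome(spec, proteome)
    db = build_db(proteome, observations, samples)
    candidates, cand_manifest = generate_candidates(spec, proteome, db)

    write_proteome(proteome, out / "proteome.fasta")
    pd.DataFrame(
        [(o.sequence, o.sample_id, o.hla_class) for o in observations],
        columns=["sequence", "sample", "hla_class"],
    ).to_csv(out / "peptides.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(s.sample_id, s.group, s.hla2_peptide_count) for s in samples],
        columns=["sample_id", "group", "hla2_peptide_count"],
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)

    truth = {
        "spec": {k: v for k, v in asdict(spec).items() if not isinstance(v, dict)},
        "proteome": prot_manifest,
        "peptidome": pep_manifest,
        "candidates": cand_manifest,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str) + "\n")
    return truth
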