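"""MS-based neoantigen features: database matching of wild-type counterparts.

For each candidate neoantigen the wild-type (wt) peptide is matched against
the immunopeptidome database, yielding three features:

* ``nrMatchingPeptides_I`` — number of unique class-I peptides of the
  candidate's source protein found in the database (protein level);
* ``matchScore_I`` — the class-I density profile summed over the wt peptide's
  placement, maximized over all of its placements (peptide level);
* ``exactMatchScore_I`` — equal to ``matchScore_I`` if the wt peptide itself
  is a class-I database peptide, else 0.

Matches are also classified as exact (wt detected by MS), included (wt is a
substring of a longer detected peptide), partial (a detected peptide covers
the mutated position), or none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage_profiles import density_profile
from .peptidome_db import AA_ALPHABET, PeptidomeDB

logger = logging.getLogger(__name__)

MATCH_TYPES = ("exact", "included", "partial", "none")

#: feature columns expected in a candidate table
FEATURE_COLUMNS = [
    "mutAffinity",
    "wtAffinity",
    "mutPeptideStability",
    "wtPeptideStability",
    "mutCleavProb",
    "wtCleavProb",
    "mutReads",
    "wtReads",
    "rnaExpr",
]

CANDIDATE_COLUMNS = [
    "candidate_id",
    "mut_peptide",
    "wt_peptide",
    "mutation_pos",
    "protein_id",
] + FEATURE_COLUMNS


@dataclass(frozen=True)
class MatchResult:
    candidate_id: str
    match_type: str
    nrMatchingPeptides_I: int
    matchScore_I: float
    exactMatchScore_I: float
    best_placement: tuple[str, int, int] | None


def load_candidates(path, sep: str | None = None, require_label: bool = False) -> pd.DataFrame:
    """Read a neoantigen candidate table (delimited text) into a DataFrame."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = list(CANDIDATE_COLUMNS)
    if require_label:
        required.append("immunogenic")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table {path} is missing column(s) {missing}")
    df["candidate_id"] = df["candidate_id"].astype(str)
    return df


def validate_candidate_row(mut_peptide: str, wt_peptide: str, mutation_pos: int) -> str | None:
    """Return an error message if a mut/wt pair violates its invariants, else None."""
    if len(mut_peptide) != len(wt_peptide):
        return "mut and wt peptides have different lengths"
    if not (0 <= mutation_pos < len(wt_peptide)):
        return f"mutation_pos {mutation_pos} out of range for length {len(wt_peptide)}"
    if not (set(mut_peptide) <= AA_ALPHABET and set(wt_peptide) <= AA_ALPHABET):
        return "non-amino-acid characters in peptide"
    diffs = [i for i, (a, b) in enumerate(zip(mut_peptide, wt_peptide)) if a != b]
    if diffs != [mutation_pos]:
        return f"mut and wt differ at positions {diffs}, expected exactly [{mutation_pos}]"
    return None


# ----------------------------------------------------------------- features
def nr_matching_peptides(db: PeptidomeDB, protein_id: str) -> int:
    """Number of unique class-I database peptides mapped to a protein (0 if absent)."""
    if protein_id not in db.placements_by_protein:
        return 0
    class1 = db.class1_peptides
    return len({pep for (pep, _, _) in db.placements_by_protein[protein_id] if pep in class1})


def find_placements(db: PeptidomeDB, peptide: str) -> list[tuple[str, int, int]]:
    """All exact placements of a query peptide in the proteome (not only db peptides)."""
    placements = []
    query = peptide.replace("I", "L") if db.collapse_il else peptide
    for pid, prot in db.proteins.items():
        seq = prot.sequence.replace("I", "L") if db.collapse_il else prot.sequence
        start = seq.find(query)
        while start != -1:
            placements.append((pid, start, start + len(peptide)))
            start = seq.find(query, start + 1)
    placements.sort()
    return placements


def match_score(db: PeptidomeDB, wt_peptide: str) -> tuple[float, tuple[str, int, int] | None]:
    """Class-I profile height summed over the wt peptide's placement.

    When the peptide places in several proteins or several times in one
    protein, the maximal sum is taken; ties are broken by (protein_id, start)
    order for determinism.  Returns (0, None) for a peptide absent from the
    proteome.
    """
    if not wt_peptide:
        raise ValueError("wt_peptide must be non-empty")
    best_score = 0.0
    best_placement = None
    for (pid, start, end) in find_placements(db, wt_peptide):
        profile = density_profile(db, pid, "I")
        score = float(profile.heights[start:end].sum())
        if best_placement is None or score > best_score:
            best_score, best_placement = score, (pid, start, end)
    if best_placement is None:
        return 0.0, None
    return best_score, best_placement


def exact_match_score(db: PeptidomeDB, wt_peptide: str) -> float:
    """matchScore_I gated on exact class-I database membership."""
    if wt_peptide not in db.class1_peptides:
        return 0.0
    return match_score(db, wt_peptide)[0]


def classify_match(db: PeptidomeDB, wt_peptide: str, mutation_pos: int) -> str:
    """Classify how a wt peptide is represented in the database.

    exact: the wt sequence itself was detected (either HLA class);
    included: wt is a proper substring of a longer detected peptide;
    partial: at some placement of wt, a detected peptide covers the absolute
    position of the mutation; none: otherwise.
    """
    if not (0 <= mutation_pos < len(wt_peptide)):
        raise ValueError(
            f"mutation_pos {mutation_pos} out of range for peptide of length {len(wt_peptide)}"
        )
    key = (lambda s: s.replace("I", "L")) if db.collapse_il else (lambda s: s)
    query = key(wt_peptide)
    all_peps = db.class1_peptides | db.class2_peptides
    if db.collapse_il:
        if query in {key(p) for p in all_peps}:
            return "exact"
    elif wt_peptide in all_peps:
        return "exact"
    for pep in all_peps:
        if len(pep) > len(wt_peptide) and query in key(pep):
            return "included"
    for (pid, start, _end) in find_placements(db, wt_peptide):
        abs_pos = start + mutation_pos
        for (_pep, q_start, q_end) in db.placements_by_protein.get(pid, ()):
            if q_start <= abs_pos < q_end:
                return "partial"
    return "none"


def score_candidates(db: PeptidomeDB, candidates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every candidate; returns (scored table, per-row error report).

    The scored table is the input joined with match_type, the three MS
    features and the best placement.  Rows violating the mut/wt invariants
    are diverted to the error report; the remainder is processed.  Output is
    deterministic given the database and the input order.
    """
    scored_rows = []
    error_rows = []
    for row in candidates.itertuples(index=False):
        err = validate_candidate_row(row.mut_peptide, row.wt_peptide, int(row.mutation_pos))
        if err is not None:
            error_rows.append({"candidate_id": row.candidate_id, "error": err})
            continue
        ms, placement = match_score(db, row.wt_peptide)
        ems = ms if row.wt_peptide in db.class1_peptides else 0.0
        rec = row._asdict()
        rec.update(
            match_type=classify_match(db, row.wt_peptide, int(row.mutation_pos)),
            nrMatchingPeptides_I=nr_matching_peptides(db, row.protein_id),
            matchScore_I=ms,
            exactMatchScore_I=ems,
            best_protein=placement[0] if placement else "",
            best_start=placement[1] if placement else -1,
            best_end=placement[2] if placement else -1,
        )
        scored_rows.append(rec)
    if error_rows:
        logger.warning("rejected %d invalid candidate row(s)", len(error_rows))
    scored = pd.DataFrame(scored_rows)
    errors = pd.DataFrame(error_rows, columns=["candidate_id", "error"])
    return scored, errors


# --------------------------------------------------------------- statistics
def enrichment_fraction(k: int, n: int) -> float:
    """Percentage 100·k/n (full precision; display rounding is the caller's)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    return 100.0 * k / n


def presence_probability(m: int, n: int, k: int) -> float:
    """Probability (m/n)^k that k independent hits all fall among m of n items."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= m <= n) or k < 0:
        raise ValueError("require 0 <= m <= n and k >= 0")
    return float((m / n) ** k)
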