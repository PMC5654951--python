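"""Immunopeptidome database: proteome + MS-observed HLA peptides.

Reads a proteome (FASTA) and peptide identification tables, deduplicates
peptides per HLA class, and maps every unique peptide sequence onto every
exact placement in the proteome.  The resulting :class:`PeptidomeDB` is the
substrate for coverage profiles, hotspot detection and neoantigen scoring.

Coordinates are 0-based half-open internally; human-readable exports use
1-based inclusive positions.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: the 20 standard residues plus X (unknown)
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: peptides shorter than this are below credible HLA ligand length
MIN_PEPTIDE_LENGTH = 7

#: samples with fewer HLA-II peptides than this are called HLA-II non-expressing
HLA2_EXPRESSION_THRESHOLD = 100

#: class-I peptides of length < this bound form the "I_short" selector
SHORT_CLASS1_MAX_LENGTH = 15

VALID_CLASSES = ("I", "II")
VALID_SELECTORS = ("I", "II", "I/II", "I_short")

DB_FORMAT_VERSION = "1"


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: opaque identifier plus amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one biological sample.

    ``hla2_expressing`` is derived: a sample counts as HLA-II expressing iff
    at least :data:`HLA2_EXPRESSION_THRESHOLD` HLA-II peptides were detected
    in it.
    """

    sample_id: str
    group: str = "other"
    hla2_peptide_count: int = 0

    @property
    def hla2_expressing(self) -> bool:
        return self.hla2_peptide_count >= HLA2_EXPRESSION_THRESHOLD


@dataclass(frozen=True)
class PeptideObservation:
    """One MS-observed peptide in one sample, with its HLA class label."""

    sequence: str
    sample_id: str
    hla_class: str

    def __post_init__(self) -> None:
        if self.hla_class not in VALID_CLASSES:
            raise ValueError(f"hla_class must be one of {VALID_CLASSES}, got {self.hla_class!r}")


Placement = tuple[str, int, int]  # (protein_id, start, end) half-open


def _collapse_il(seq: str) -> str:
    return seq.replace("I", "L")


@dataclass
class PeptidomeDB:
    """Deduplicated peptide sets per HLA class with an exact occurrence index.

    Attributes
    ----------
    proteins
        Mapping protein_id -> :class:`ProteinRecord`, in input order.
    class1_peptides, class2_peptides
        Unique peptide sequences observed in HLA-I / HLA-II samples.
    occurrence_index
        Mapping sequence -> sorted list of exact placements ``(protein_id,
        start, end)`` (0-based half-open).  Sequences with no placement are
        present with an empty list and also recorded in ``unmapped``.
    collapse_il
        Whether isoleucine/leucine were collapsed for matching (MS cannot
        distinguish them).  Off by default to preserve exactness.
    """

    proteins: dict[str, ProteinRecord]
    class1_peptides: set[str]
    class2_peptides: set[str]
    occurrence_index: dict[str, list[Placement]]
    samples: dict[str, SampleMeta]
    observations_by_sample: dict[str, list[PeptideObservation]]
    unmapped: set[str]
    collapse_il: bool = False
    razor: bool = False
    # reverse index: protein_id -> list of (sequence, start, end)
    placements_by_protein: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    _profile_cache: dict = field(default_factory=dict, repr=False)

    @property
    def shared_peptides(self) -> set[str]:
        return self.class1_peptides & self.class2_peptides

    def peptides_for_selector(self, selector: str) -> set[str]:
        """Unique peptide sequences belonging to a class selector."""
        if selector == "I":
            return self.class1_peptides
        if selector == "II":
            return self.class2_peptides
        if selector == "I/II":
            return self.shared_peptides
        if selector == "I_short":
            return {p for p in self.class1_peptides if len(p) < SHORT_CLASS1_MAX_LENGTH}
        raise ValueError(f"unknown class selector {selector!r}; expected one of {VALID_SELECTORS}")

    def mapped_peptides(self, selector: str) -> set[str]:
        return {p for p in self.peptides_for_selector(selector) if self.occurrence_index.get(p)}

    # ------------------------------------------------------------------ io
    def save(self, out_dir: str | Path) -> Path:
        """Serialize as a directory of delimited tables plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [(p.protein_id, p.sequence) for p in self.proteins.values()],
            columns=["protein_id", "sequence"],
        ).to_csv(out / "proteins.tsv", sep="\t", index=False)

        pep_rows = []
        for cls, peps in (("I", self.class1_peptides), ("II", self.class2_peptides)):
            for seq in sorted(peps):
                pep_rows.append((seq, cls, int(seq in self.unmapped)))
        pd.DataFrame(pep_rows, columns=["sequence", "hla_class", "unmapped"]).to_csv(
            out / "peptides.tsv", sep="\t", index=False
        )

        occ_rows = [
            (seq, pid, s, e)
            for seq in sorted(self.occurrence_index)
            for (pid, s, e) in self.occurrence_index[seq]
        ]
        pd.DataFrame(occ_rows, columns=["sequence", "protein_id", "start", "end"]).to_csv(
            out / "occurrences.tsv", sep="\t", index=False
        )

        pd.DataFrame(
            [(s.sample_id, s.group, s.hla2_peptide_count) for s in self.samples.values()],
            columns=["sample_id", "group", "hla2_peptide_count"],
        ).to_csv(out / "samples.tsv", sep="\t", index=False)

        obs_rows = [
            (o.sequence, o.sample_id, o.hla_class)
            for sid in sorted(self.observations_by_sample)
            for o in self.observations_by_sample[sid]
        ]
        pd.DataFrame(obs_rows, columns=["sequence", "sample_id", "hla_class"]).to_csv(
            out / "observations.tsv", sep="\t", index=False
        )

        manifest = {
            "format_version": DB_FORMAT_VERSION,
            "collapse_il": self.collapse_il,
            "razor": self.razor,
            "n_proteins": len(self.proteins),
            "n_class1": len(self.class1_peptides),
            "n_class2": len(self.class2_peptides),
            "n_shared": len(self.shared_peptides),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return out

    @classmethod
    def load(cls, db_dir: str | Path) -> "PeptidomeDB":
        """Rebuild a database from its serialized form (see :meth:`save`)."""
        d = Path(db_dir)
        manifest = json.loads((d / "manifest.json").read_text())
        prot_df = pd.read_csv(d / "proteins.tsv", sep="\t", dtype=str)
        proteins = [ProteinRecord(r.protein_id, r.sequence) for r in prot_df.itertuples()]
        samp_df = pd.read_csv(d / "samples.tsv", sep="\t")
        samples = [
            SampleMeta(str(r.sample_id), str(r.group), int(r.hla2_peptide_count))
            for r in samp_df.itertuples()
        ]
        obs_df = pd.read_csv(d / "observations.tsv", sep="\t", dtype=str)
        observations = [
            PeptideObservation(r.sequence, r.sample_id, r.hla_class) for r in obs_df.itertuples()
        ]
        return build_db(
            proteins,
            observations,
            samples,
            collapse_il=manifest["collapse_il"],
            razor=manifest["razor"],
        )


# ---------------------------------------------------------------------- load
def load_proteome(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA into :class:`ProteinRecord` objects, in file order.

    The identifier is the first whitespace-delimited header token.  Sequences
    are uppercased and terminal ``*`` stop characters stripped.  Duplicate
    identifiers and empty files are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein identifier {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper().strip("*")
        records.append(ProteinRecord(pid, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_proteome(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")


def _is_valid_peptide(seq: str) -> bool:
    return bool(seq) and set(seq) <= AA_ALPHABET


def load_peptide_table(
    path: str | Path,
    dialect: str = "plain",
    sample_id: str | None = None,
    hla_class: str | None = None,
    sep: str | None = None,
) -> list[PeptideObservation]:
    """Read a delimited peptide identification table.

    ``plain`` dialect requires columns ``sequence``, ``sample``, ``hla_class``.
    ``maxquant`` dialect requires at least a ``Sequence`` column (a reduced
    peptides.txt) and takes the sample and class as arguments.  Rows whose
    sequence contains non-amino-acid characters, or is shorter than
    :data:`MIN_PEPTIDE_LENGTH`, are dropped with a logged count.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)

    if dialect == "plain":
        required = ["sequence", "sample", "hla_class"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"peptide table {path} is missing column(s) {missing}; expected {required}"
            )
        rows = df[required].itertuples(index=False)
        triples = [(r.sequence, r.sample, r.hla_class) for r in rows]
    elif dialect == "maxquant":
        if "Sequence" not in df.columns:
            raise ValueError(
                f"maxquant table {path} is missing the 'Sequence' column"
            )
        if sample_id is None or hla_class is None:
            raise ValueError("maxquant dialect requires sample_id and hla_class arguments")
        triples = [(s, sample_id, hla_class) for s in df["Sequence"]]
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'plain' or 'maxquant'")

    observations: list[PeptideObservation] = []
    n_bad_alphabet = 0
    n_short = 0
    for seq, sid, cls in triples:
        seq = str(seq).upper()
        if not _is_valid_peptide(seq):
            n_bad_alphabet += 1
            continue
        if len(seq) < MIN_PEPTIDE_LENGTH:
            n_short += 1
            continue
        observations.append(PeptideObservation(seq, str(sid), str(cls)))
    if n_bad_alphabet:
        logger.warning(
            "%s: dropped %d row(s) with non-amino-acid characters", path, n_bad_alphabet
        )
    if n_short:
        logger.warning(
            "%s: dropped %d row(s) shorter than %d residues", path, n_short, MIN_PEPTIDE_LENGTH
        )
    return observations


def load_samples(path: str | Path, sep: str = "\t") -> list[SampleMeta]:
    """Read a sample metadata table with columns sample_id, group, hla2_peptide_count."""
    df = pd.read_csv(path, sep=sep)
    required = ["sample_id", "group", "hla2_peptide_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} is missing column(s) {missing}; expected {required}")
    return [
        SampleMeta(str(r.sample_id), str(r.group), int(r.hla2_peptide_count))
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------- build
def _find_placements_indexed(
    proteins: dict[str, ProteinRecord], peptides: set[str], collapse_il: bool
) -> dict[str, list[Placement]]:
    """Exact multi-pattern matching via per-length windowed hash lookup.

    For each distinct peptide length L, every length-L window of every protein
    is looked up in a hash set, so the cost is O(total protein length × number
    of distinct lengths) regardless of peptide count.
    """
    key = _collapse_il if collapse_il else (lambda s: s)
    by_length: dict[int, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    for pep in peptides:
        by_length[len(pep)][key(pep)].append(pep)

    index: dict[str, list[Placement]] = {pep: [] for pep in peptides}
    for prot in proteins.values():
        seq = key(prot.sequence)
        n = len(seq)
        for length, lookup in by_length.items():
            if length > n:
                continue
            for start in range(n - length + 1):
                window = seq[start : start + length]
                hits = lookup.get(window)
                if hits:
                    for pep in hits:
                        index[pep].append((prot.protein_id, start, start + length))
    for placements in index.values():
        placements.sort()
    return index


def build_db(
    proteins: list[ProteinRecord] | dict[str, ProteinRecord],
    observations: list[PeptideObservation],
    samples: list[SampleMeta] | dict[str, SampleMeta],
    collapse_il: bool = False,
    razor: bool = False,
) -> PeptidomeDB:
    """Assemble a :class:`PeptidomeDB` from proteome, observations and samples.

    Class sets are deduplicated over sequences; the occurrence index records
    every exact placement of every unique sequence in every protein.  With
    ``razor=True`` each peptide is restricted to a single best protein (the
    protein accumulating most peptides, ties broken by lexicographic id),
    approximating razor-protein assignment.  Unknown sample ids are hard
    errors; peptides with zero placements are kept in the class sets but
    flagged unmapped.
    """
    if isinstance(proteins, dict):
        prot_map = dict(proteins)
    else:
        prot_map = {}
        for p in proteins:
            if p.protein_id in prot_map:
                raise ValueError(f"duplicate protein identifier {p.protein_id!r}")
            prot_map[p.protein_id] = p
    samp_map = (
        dict(samples) if isinstance(samples, dict) else {s.sample_id: s for s in samples}
    )

    class1: set[str] = set()
    class2: set[str] = set()
    obs_by_sample: dict[str, list[PeptideObservation]] = defaultdict(list)
    for obs in observations:
        if obs.sample_id not in samp_map:
            raise ValueError(f"observation references unknown sample_id {obs.sample_id!r}")
        (class1 if obs.hla_class == "I" else class2).add(obs.sequence)
        obs_by_sample[obs.sample_id].append(obs)

    all_peps = class1 | class2
    index = _find_placements_indexed(prot_map, all_peps, collapse_il)

    if razor:
        # razor protein = argmax over proteins of total mapped peptides,
        # ties by lexicographic protein id
        per_protein_total: dict[str, int] = defaultdict(int)
        for placements in index.values():
            for pid in {p for (p, _, _) in placements}:
                per_protein_total[pid] += 1
        for pep, placements in index.items():
            if not placements:
                continue
            best = min(
                {p for (p, _, _) in placements},
                key=lambda pid: (-per_protein_total[pid], pid),
            )
            index[pep] = [pl for pl in placements if pl[0] == best]

    unmapped = {pep for pep, placements in index.items() if not placements}
    if unmapped:
        logger.info("%d peptide sequence(s) have no placement in the proteome", len(unmapped))

    by_protein: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for pep in sorted(index):
        for (pid, s, e) in index[pep]:
            by_protein[pid].append((pep, s, e))
    for placements in by_protein.values():
        placements.sort(key=lambda t: (t[1], t[2], t[0]))

    return PeptidomeDB(
        proteins=prot_map,
        class1_peptides=class1,
        class2_peptides=class2,
        occurrence_index=index,
        samples=samp_map,
        observations_by_sample=dict(obs_by_sample),
        unmapped=unmapped,
        collapse_il=collapse_il,
        razor=razor,
        placements_by_protein=dict(by_protein),
    )


# ------------------------------------------------------------------- summary
@dataclass(frozen=True)
class DBSummary:
    n_class1: int
    n_class2: int
    n_shared: int
    shared_percentage: float
    n_proteins_mapped: int
    length_histogram_class1: dict[int, int]
    length_histogram_class2: dict[int, int]


def shared_percentage(n_class1: int, n_class2: int, n_shared: int) -> float:
    """Shared-peptide percentage: 100·|shared| / (|I| + |II|).

    The denominator is the sum of the class counts, not the union.  Returns
    0.0 when either class set is empty.
    """
    if n_class1 == 0 or n_class2 == 0:
        return 0.0
    return 100.0 * n_shared / (n_class1 + n_class2)


def _length_hist(peptides: set[str]) -> dict[int, int]:
    hist: dict[int, int] = defaultdict(int)
    for p in peptides:
        hist[len(p)] += 1
    return dict(sorted(hist.items()))


def db_summary(db: PeptidomeDB) -> DBSummary:
    """Database-level counts: unique peptides per class, sharing, mapped proteins."""
    n1, n2 = len(db.class1_peptides), len(db.class2_peptides)
    shared = db.shared_peptides
    mapped_proteins = {
        pid for placements in db.occurrence_index.values() for (pid, _, _) in placements
    }
    return DBSummary(
        n_class1=n1,
        n_class2=n2,
        n_shared=len(shared),
        shared_percentage=shared_percentage(n1, n2, len(shared)),
        n_proteins_mapped=len(mapped_proteins),
        length_histogram_class1=_length_hist(db.class1_peptides),
        length_histogram_class2=_length_hist(db.class2_peptides),
    )


def peptides_per_protein(db: PeptidomeDB, class_selector: str) -> dict[str, int]:
    """Count unique mapped peptides of a selector per protein.

    A peptide placed at several positions of one protein is counted once for
    that protein; a peptide matching several proteins counts in each.
    Proteins without any mapped peptide of the selector are absent from the
    result.
    """
    selected = db.peptides_for_selector(class_selector)
    per_protein: dict[str, set[str]] = defaultdict(set)
    for pep in selected:
        for (pid, _, _) in db.occurrence_index.get(pep, ()):
            per_protein[pid].add(pep)
    return {pid: len(peps) for pid, peps in sorted(per_protein.items())}
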