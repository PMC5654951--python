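import numpy as np
import pytest

import immunopep as ip


@pytest.fixture(scope="session")
def toy_db():
    """Single protein ACDEFGHIKL covered by three class-I 5-mers, one of
    which (DEFGH) was also seen in a class-II sample; all worked examples on
    this toy are checkable by hand."""
    proteins = [ip.ProteinRecord("P1", "ACDEFGHIKL")]
    samples = [ip.SampleMeta("s1", "B-cells", 0), ip.SampleMeta("s2", "B-cells", 150)]
    observations = [
        ip.PeptideObservation("ACDEF", "s1", "I"),
        ip.PeptideObservation("DEFGH", "s1", "I"),
        ip.PeptideObservation("GHIKL", "s1", "I"),
        ip.PeptideObservation("DEFGH", "s2", "II"),
    ]
    return ip.build_db(proteins, observations, samples)


def _make_random_db(rng, n_proteins=8, protein_len=(60, 120), n_peptides=60, alphabet="ACDEFG"):
    """Small random database over a reduced alphabet (forces repeat matches)."""
    proteins = [
        ip.ProteinRecord(
            f"R{i}",
            "".join(rng.choice(list(alphabet), size=int(rng.integers(*protein_len)))),
        )
        for i in range(n_proteins)
    ]
    samples = [ip.SampleMeta("s1", "B-cells", 150)]
    observations = []
    for _ in range(n_peptides):
        cls = "I" if rng.random() < 0.7 else "II"
        L = int(rng.integers(7, 12 if cls == "I" else 16))
        if rng.random() < 0.85:  # true substring
            prot = proteins[int(rng.integers(n_proteins))]
            if len(prot.sequence) <= L:
                continue
            s = int(rng.integers(0, len(prot.sequence) - L))
            seq = prot.sequence[s : s + L]
        else:  # junk peptide, possibly unmapped
            seq = "".join(rng.choice(list(alphabet), size=L))
        observations.append(ip.PeptideObservation(seq, "s1", cls))
    return ip.build_db(proteins, observations, samples)


@pytest.fixture
def make_random_db():
    return _make_random_db


@pytest.fixture(scope="session")
def synth():
    """One default synthetic study shared by the slower integration tests."""
    spec = ip.GeneratorSpec(seed=101)
    proteome, prot_manifest = ip.generate_proteome(spec)
    observations, samples, pep_manifest = ip.generate_peptidome(spec, proteome)
    db = ip.build_db(proteome, observations, samples)
    candidates, cand_manifest = ip.generate_candidates(spec, proteome, db)
    scored, errors = ip.score_candidates(db, candidates)
    assert errors.empty
    return {
        "spec": spec,
        "proteome": proteome,
        "observations": observations,
        "samples": samples,
        "db": db,
        "candidates": candidates,
        "scored": scored,
        "prot_manifest": prot_manifest,
        "pep_manifest": pep_manifest,
        "cand_manifest": cand_manifest,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
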