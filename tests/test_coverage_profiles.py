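import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import immunopep as ip
from immunopep.coverage_profiles import segment_hotspots

from _oracles import interval_jaccard, naive_hotspot_runs, naive_profile


class TestDensityProfile:
    def test_toy_class1_heights(self, toy_db):
        prof = ip.density_profile(toy_db, "P1", "I")
        assert prof.heights.tolist() == [1, 1, 2, 2, 2, 2, 2, 1, 1, 1]

    def test_toy_shared_heights(self, toy_db):
        prof = ip.density_profile(toy_db, "P1", "I/II")
        assert prof.heights.tolist() == [0, 0, 1, 1, 1, 1, 1, 0, 0, 0]

    def test_unknown_protein_is_hard_error(self, toy_db):
        with pytest.raises(KeyError):
            ip.density_profile(toy_db, "NOPE", "I")

    def test_protein_without_peptides_all_zero(self):
        proteins = [ip.ProteinRecord("P1", "ACDEFGHIKL"), ip.ProteinRecord("P2", "WWWWWWWWWW")]
        db = ip.build_db(
            proteins, [ip.PeptideObservation("ACDEF", "s1", "I")], [ip.SampleMeta("s1")]
        )
        assert ip.density_profile(db, "P2", "I").heights.tolist() == [0] * 10

    def test_repeated_placement_contributes_twice(self):
        proteins = [ip.ProteinRecord("P1", "ACDEFACDEF")]
        db = ip.build_db(
            proteins, [ip.PeptideObservation("ACDEF", "s1", "I")], [ip.SampleMeta("s1")]
        )
        assert ip.density_profile(db, "P1", "I").heights.tolist() == [1] * 10

    def test_matches_naive_counting_oracle(self, make_random_db, rng):
        for _ in range(5):
            db = make_random_db(rng)
            proteins = {p.protein_id: p.sequence for p in db.proteins.values()}
            mapped1 = db.mapped_peptides("I")
            for pid in proteins:
                got = ip.density_profile(db, pid, "I").heights.tolist()
                assert got == naive_profile(proteins, mapped1, pid)

    def test_conservation_and_selector_order(self, synth):
        """sum(heights) equals total placement length; I_short <= I pointwise."""
        db = synth["db"]
        rng = np.random.default_rng(0)
        pids = rng.choice(list(db.proteins), size=25, replace=False)
        for pid in pids:
            for sel in ("I", "II", "I/II", "I_short"):
                prof = ip.density_profile(db, pid, sel)
                selected = db.peptides_for_selector(sel)
                total = sum(
                    e - s
                    for (pep, s, e) in db.placements_by_protein.get(pid, ())
                    if pep in selected
                )
                assert int(prof.heights.sum()) == total
            assert (
                ip.density_profile(db, pid, "I_short").heights
                <= ip.density_profile(db, pid, "I").heights
            ).all()

    def test_adding_a_peptide_never_decreases_heights(self):
        proteins = [ip.ProteinRecord("P1", "ACDEFGHIKLMNPQRSTVWY")]
        samples = [ip.SampleMeta("s1")]
        obs = [ip.PeptideObservation("ACDEFGHIK", "s1", "I")]
        before = ip.density_profile(ip.build_db(proteins, obs, samples), "P1", "I").heights
        obs2 = obs + [ip.PeptideObservation("FGHIKLMNP", "s1", "I")]
        after = ip.density_profile(ip.build_db(proteins, obs2, samples), "P1", "I").heights
        assert (after >= before).all()


def _profile_from_heights(heights):
    return ip.DensityProfile("P", "I", np.asarray(heights), "A" * len(heights))


class TestSegmentHotspots:
    def test_toy_single_run(self):
        hs = segment_hotspots(_profile_from_heights([1, 1, 2, 2, 2, 2, 2, 1, 1, 1]), 2, 0.0, 0)
        assert len(hs) == 1
        assert (hs[0].start, hs[0].end, hs[0].peak_height, hs[0].area) == (2, 7, 2, 10)

    def test_all_zero_profile_yields_nothing(self):
        assert segment_hotspots(_profile_from_heights([0, 0, 0]), 2, 0.0, 0) == []

    def test_merge_gap_joins_runs(self):
        hs = segment_hotspots(_profile_from_heights([3, 0, 3]), 1, 0.0, 2)
        assert len(hs) == 1
        assert (hs[0].start, hs[0].end, hs[0].peak_height, hs[0].area) == (0, 3, 3, 6)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            segment_hotspots(_profile_from_heights([1]), -1, 0.0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        heights=st.lists(st.integers(min_value=0, max_value=6), min_size=1, max_size=40),
        min_height=st.integers(min_value=1, max_value=5),
        merge_gap=st.integers(min_value=0, max_value=4),
    )
    def test_agrees_with_run_length_oracle(self, heights, min_height, merge_gap):
        hs = segment_hotspots(_profile_from_heights(heights), min_height, 0.0, merge_gap)
        if max(heights) == 0:
            assert hs == []
            return
        expected = naive_hotspot_runs(heights, min_height, merge_gap)
        assert [(h.start, h.end) for h in hs] == expected
        # disjoint, sorted, and peak/area consistent
        for a, b in zip(hs, hs[1:]):
            assert a.end <= b.start
        for h in hs:
            assert h.peak_height == max(heights[h.start : h.end])
            assert h.area == sum(heights[h.start : h.end])


class TestMainPeakCorrelation:
    def test_identical_profiles(self):
        p = _profile_from_heights([0, 1, 5, 5, 1, 0])
        assert ip.main_peak_correlation(p, p) == 1.0

    def test_disjoint_masks(self):
        a = _profile_from_heights([5, 5, 0, 0, 0, 0])
        b = _profile_from_heights([0, 0, 0, 0, 5, 5])
        assert ip.main_peak_correlation(a, b) == 0.0

    def test_partial_overlap_jaccard(self):
        # masks {2..7} vs {3..9}: intersection 5, union 8
        a = _profile_from_heights([0, 0, 4, 4, 4, 4, 4, 4, 0, 0, 1])
        b = _profile_from_heights([0, 0, 0, 4, 4, 4, 4, 4, 4, 4, 1])
        assert ip.main_peak_correlation(a, b, peak_frac=0.5) == pytest.approx(5 / 8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ip.main_peak_correlation(_profile_from_heights([1]), _profile_from_heights([1, 2]))

    def test_empty_profile_scores_zero(self):
        a = _profile_from_heights([0, 0, 0])
        b = _profile_from_heights([1, 1, 0])
        assert ip.main_peak_correlation(a, b) == 0.0


class TestHotspotOverlap:
    def test_shared_inside_class2_hotspot_gives_full_overlap(self):
        # one protein where the shared peptide region is densely covered by
        # class-II peptides
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        proteins = [ip.ProteinRecord("P1", seq)]
        samples = [ip.SampleMeta("s1", "B-cells", 150)]
        obs = []
        for start in (2, 3, 4):
            obs.append(ip.PeptideObservation(seq[start : start + 12], "s1", "II"))
        for cls in ("I", "II"):  # two shared 9-mers inside the class-II pile
            obs.append(ip.PeptideObservation(seq[4:13], "s1", cls))
            obs.append(ip.PeptideObservation(seq[5:14], "s1", cls))
        db = ip.build_db(proteins, obs, samples)
        stats = ip.hotspot_overlap_stats(db, min_height=2)
        assert stats["mean_overlap_II"] == 1.0

    def test_no_shared_hotspots_gives_empty_result(self, toy_db):
        stats = ip.hotspot_overlap_stats(toy_db, min_height=2)
        assert stats["per_protein"].empty
        assert stats["mean_overlap_II"] is None

    def test_planted_overlap_rates_recovered(self, synth):
        db = synth["db"]
        man = synth["pep_manifest"]
        stats = ip.hotspot_overlap_stats(db, min_height=2, min_frac_of_max=0.5)
        assert stats["mean_overlap_II"] == pytest.approx(man["realized_overlap_ii"], abs=0.1)
        assert stats["mean_overlap_I"] == pytest.approx(man["realized_overlap_i"], abs=0.1)
        # the shared hotspots overlap class-II hotspots more often (direction
        # of the planted asymmetry)
        assert stats["mean_overlap_II"] > stats["mean_overlap_I"]


class TestLengthDistribution:
    def test_single_peptide(self):
        proteins = [ip.ProteinRecord("P1", "ACDEFGHIKLMN")]
        db = ip.build_db(
            proteins, [ip.PeptideObservation("ACDEFGHIKLMN", "s1", "I")], [ip.SampleMeta("s1")]
        )
        dist = ip.length_distribution(db, "I")
        assert dist.counts == {12: 1}
        assert dist.modal_length == 12

    def test_synthetic_modes(self, synth):
        db = synth["db"]
        assert ip.length_distribution(db, "I").modal_length == 9
        assert ip.length_distribution(db, "II").modal_length == 15

    def test_shared_selector_is_bimodal_mixture(self, synth):
        counts = ip.length_distribution(synth["db"], "I/II").counts
        lengths = sorted(counts)
        # shared peptides span the long class-I / class-II length range
        assert lengths[0] >= 8 and lengths[-1] >= 14


class TestLongPeptideProportion:
    def _db(self, samples, seqs_by_sample):
        proteins = [ip.ProteinRecord("P1", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY")]
        obs = [
            ip.PeptideObservation(seq, sid, "I")
            for sid, seqs in seqs_by_sample.items()
            for seq in seqs
        ]
        return ip.build_db(proteins, obs, samples)

    def test_direct_count(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        db = self._db(
            [ip.SampleMeta("s1", "B-cells", 150)],
            {"s1": [seq[0:9], seq[1:10], seq[2:12], seq[3:17]]},
        )
        rec = ip.long_peptide_proportion(db)
        assert rec["per_sample"]["long_proportion"].tolist() == [0.25]

    def test_all_short_and_all_long(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        db = self._db(
            [ip.SampleMeta("s1", "B-cells", 150), ip.SampleMeta("s2", "other", 0)],
            {"s1": [seq[0:9], seq[1:10]], "s2": [seq[0:14], seq[1:16]]},
        )
        rec = ip.long_peptide_proportion(db)
        per = rec["per_sample"].set_index("sample_id")["long_proportion"]
        assert per["s1"] == 0.0
        assert per["s2"] == 1.0

    def test_missing_group_reported_as_none(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        db = self._db([ip.SampleMeta("s1", "B-cells", 150)], {"s1": [seq[0:9]]})
        rec = ip.long_peptide_proportion(db)
        assert rec["hla2_lacking"]["mean"] is None
        assert rec["mean_difference"] is None

    def test_synthetic_groups_close_to_planted_rates(self, synth):
        rec = ip.long_peptide_proportion(synth["db"])
        # planted: 4.8% base long-peptide mass, +0.8 points when expressing
        assert rec["hla2_expressing"]["mean"] == pytest.approx(0.056, abs=0.02)
        assert rec["hla2_lacking"]["mean"] == pytest.approx(0.048, abs=0.02)


class TestExport:
    def test_bedgraph_run_length_encoding(self, tmp_path):
        prof = _profile_from_heights([1, 1, 2])
        path = ip.export_profile(prof, tmp_path / "p.bedgraph", format="bedgraph")
        assert path.read_text().splitlines() == ["P\t0\t2\t1", "P\t2\t3\t2"]

    def test_bedgraph_zero_profile(self, tmp_path):
        prof = _profile_from_heights([0, 0, 0])
        path = ip.export_profile(prof, tmp_path / "p.bedgraph", format="bedgraph")
        assert path.read_text().splitlines() == ["P\t0\t3\t0"]
        path = ip.export_profile(prof, tmp_path / "p2.bedgraph", format="bedgraph", skip_zero=True)
        assert path.read_text() == ""

    def test_tsv_round_trip(self, tmp_path, toy_db):
        prof = ip.density_profile(toy_db, "P1", "I")
        path = ip.export_profile(prof, tmp_path / "p.tsv", format="tsv")
        back = ip.read_profile_tsv(path, "P1", "I")
        assert back.heights.tolist() == prof.heights.tolist()
        assert back.sequence == prof.sequence
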