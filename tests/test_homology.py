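"""Consensus building, six-frame translation, translated search, filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evescan import (FilterPolicy, ScoringScheme, SequenceRecord,
                     build_consensus, reciprocal_classify, revcomp,
                     shortlist_hits, six_frame_translate, translated_search)
from evescan._sw import LocalScorer
from tests.conftest import AA20, back_translate, random_dna, random_protein


class TestBuildConsensus:
    def test_identical_rows(self):
        rows = [SequenceRecord(f"r{i}", "MKVLA", "protein")
                for i in range(3)]
        assert build_consensus(rows).residues == "MKVLA"

    def test_plurality_column(self):
        rows = [SequenceRecord(f"r{i}", s, "protein")
                for i, s in enumerate(["AV", "AV", "VV"])]
        assert build_consensus(rows, threshold=0.5).residues == "AV"

    def test_tie_below_threshold_gives_x(self):
        rows = [SequenceRecord("a", "A", "protein"),
                SequenceRecord("b", "V", "protein")]
        assert build_consensus(rows, threshold=0.6).residues == "X"

    def test_all_gap_columns_dropped(self):
        rows = [SequenceRecord("a", "A-K", "protein"),
                SequenceRecord("b", "A-K", "protein")]
        assert build_consensus(rows).residues == "AK"

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestSixFrameTranslate:
    def test_standard_code_all_frames(self):
        frames = six_frame_translate(SequenceRecord("c", "ATGGCC"))
        assert frames == {1: "MA", 2: "W", 3: "G",
                          -1: "GH", -2: "A", -3: "P"}

    def test_stop_codon(self):
        assert six_frame_translate(SequenceRecord("c", "TAA"))[1] == "*"

    def test_n_codon_translates_to_x(self):
        assert six_frame_translate(SequenceRecord("c", "ANG"))[1] == "X"

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=9, max_size=60))
    def test_revcomp_frames_are_a_relabelling(self, s):
        f = six_frame_translate(SequenceRecord("c", s))
        g = six_frame_translate(SequenceRecord("c", revcomp(s)))
        assert sorted(f.values()) == sorted(g.values())


class TestTranslatedSearch:
    def test_exact_plant_full_length_frame1(self, rng):
        prot = random_protein(rng, 60)
        contig = SequenceRecord("c", back_translate(prot))
        sc = ScoringScheme()
        hits = translated_search(SequenceRecord("q", prot, "protein"),
                                 [contig], sc, min_raw_score=1)
        top = hits[0]
        assert top.frame == 1
        assert top.length == 60
        expected = sum(sc.matrix[a, a] for a in prot)
        assert top.score == pytest.approx(expected)
        assert (top.subject_start, top.subject_end) == (0, 180)

    def test_reverse_strand_plant_same_score_forward_coords(self, rng):
        prot = random_protein(rng, 50)
        ins = revcomp(back_translate(prot))
        left = random_dna(rng, 99)
        contig = SequenceRecord("c", left + ins + random_dna(rng, 102))
        sc = ScoringScheme()
        hits = translated_search(SequenceRecord("q", prot, "protein"),
                                 [contig], sc, min_raw_score=1)
        top = hits[0]
        assert top.frame < 0
        assert top.score == pytest.approx(
            sum(sc.matrix[a, a] for a in prot))
        assert contig.seq[top.subject_start:top.subject_end] == ins

    def test_no_positive_pair_no_hits(self):
        # poly-proline query versus poly-A contig: frames are poly-K and
        # poly-F, and BLOSUM62 scores P against both negatively
        contig = SequenceRecord("c", "A" * 90)
        hits = translated_search(SequenceRecord("q", "P" * 20, "protein"),
                                 [contig], min_raw_score=1)
        assert hits == []

    def test_evalue_doubles_with_search_space(self, rng):
        prot = random_protein(rng, 40)
        contig = SequenceRecord("c", back_translate(prot))
        q = SequenceRecord("q", prot, "protein")
        one = translated_search(q, [contig], min_raw_score=1)
        two = translated_search(
            q, [contig, SequenceRecord("c2", contig.seq)], min_raw_score=1)
        h1 = one[0]
        h2 = [h for h in two if h.subject_id == "c" and h.frame == 1][0]
        assert h2.evalue == pytest.approx(2 * h1.evalue)
        assert h2.score == h1.score

    def test_score_matches_independent_dp_oracle(self, rng):
        scorer = LocalScorer()
        sc = ScoringScheme()
        for i in range(25):
            q = random_protein(rng, int(rng.integers(15, 120)))
            contig = SequenceRecord("c", random_dna(
                rng, int(rng.integers(90, 600))))
            if i % 3 == 0:
                ins = back_translate(q)
                if i % 2:
                    ins = revcomp(ins)
                contig = SequenceRecord("c", contig.seq + ins)
            hits = translated_search(SequenceRecord("q", q, "protein"),
                                     [contig], sc, min_raw_score=1)
            impl = max((h.score for h in hits), default=0.0)
            frames = six_frame_translate(contig)
            oracle = max(scorer.score(q, f) for f in frames.values() if f)
            assert impl == pytest.approx(oracle)


class TestShortlist:
    def _hit(self, length, evalue):
        from evescan import TranslatedHit

        return TranslatedHit("q", "s", 1, 0, 3 * length, 0, length, length,
                             length, 0, 0, 100.0, 50.0, evalue)

    def test_short_hit_discarded_despite_significance(self):
        assert shortlist_hits([self._hit(49, 1e-30)]) == []

    def test_long_insignificant_hit_discarded(self):
        assert shortlist_hits([self._hit(200, 1e-5)]) == []

    def test_passing_hit_kept_and_empty_ok(self):
        kept = shortlist_hits([self._hit(200, 1e-30)])
        assert len(kept) == 1
        assert shortlist_hits([]) == []

    def test_inverted_direction_configurable(self):
        policy = FilterPolicy(discard_significant=True)
        assert shortlist_hits([self._hit(200, 1e-30)], policy) == []
        assert len(shortlist_hits([self._hit(200, 1e-5)], policy)) == 1

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.tuples(st.integers(1, 300),
                           st.floats(1e-40, 1.0)), max_size=12),
        st.floats(1e-20, 1e-5), st.floats(1e-20, 1e-5),
        st.integers(1, 120), st.integers(1, 120),
    )
    def test_filter_monotonicity(self, specs, e1, e2, l1, l2):
        hits = [self._hit(ln, ev) for ln, ev in specs]
        loose_e, tight_e = max(e1, e2), min(e1, e2)
        loose_l, tight_l = min(l1, l2), max(l1, l2)
        # raising max E-value never removes a survivor
        a = {id(h) for h in shortlist_hits(hits, FilterPolicy(loose_l,
                                                              tight_e))}
        b = {id(h) for h in shortlist_hits(hits, FilterPolicy(loose_l,
                                                              loose_e))}
        assert a <= b
        # raising min length never adds one
        c = {id(h) for h in shortlist_hits(hits, FilterPolicy(tight_l,
                                                              loose_e))}
        assert c <= b


class TestReciprocalClassify:
    def test_planted_viral_protein_called_viral(self, rng):
        prot = random_protein(rng, 80)
        region = SequenceRecord("r", back_translate(prot))
        viral = [SequenceRecord("vp", prot, "protein")]
        shuffled = "".join(rng.permutation(list(prot)))
        decoys = [SequenceRecord("hp", shuffled, "protein")]
        call = reciprocal_classify(region, viral, decoys)
        assert call.verdict == "viral"

    def test_host_orf_called_false_positive(self, rng):
        host_prot = random_protein(rng, 80)
        region = SequenceRecord("r", back_translate(host_prot))
        viral = [SequenceRecord("vp", random_protein(rng, 80), "protein")]
        non_viral = [SequenceRecord("hp", host_prot, "protein")]
        call = reciprocal_classify(region, viral, non_viral)
        assert call.verdict == "false-positive"

    def test_exact_tie_is_ambiguous(self, rng):
        prot = random_protein(rng, 60)
        region = SequenceRecord("r", back_translate(prot))
        call = reciprocal_classify(
            region,
            [SequenceRecord("vp", prot, "protein")],
            [SequenceRecord("hp", prot, "protein")])
        assert call.verdict == "ambiguous"

    def test_empty_database_rejected(self, rng):
        region = SequenceRecord("r", random_dna(rng, 90))
        with pytest.raises(ValueError):
            reciprocal_classify(region, [], [SequenceRecord(
                "hp", "MKV", "protein")])
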