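"""TMR array detection, motif orientation, junction calls, terminal overlaps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evescan import (SequenceRecord, build_host, build_viral_genome,
                     call_junction, canonical_motif, embed_viral_insertion,
                     find_tmr_arrays, motif_orientation, revcomp,
                     terminal_overlap)
from tests.conftest import random_dna


class _Hit:
    def __init__(self, start, end, qid="vq"):
        self.subject_start = start
        self.subject_end = end
        self.query_id = qid


class TestFindTMRArrays:
    def test_perfect_array(self):
        rec = SequenceRecord("c", "TTAGGG" * 10)
        arrays = find_tmr_arrays(rec, "TTAGGG")
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.copies, a.purity) == (10, 1.0)
        assert (a.start, a.end) == (0, 60)

    def test_one_degraded_copy_purity(self):
        rec = SequenceRecord(
            "c", "ACGTAC" + "TTAGGG" * 5 + "TTACGG" + "TTAGGG" * 5 + "GCATAC")
        arrays = find_tmr_arrays(rec, "TTAGGG", min_copies=3, max_gap=6)
        assert len(arrays) == 1
        assert arrays[0].copies == 10
        assert arrays[0].purity == pytest.approx(10 / 11)

    def test_no_motif_empty(self, rng):
        # alphabet without G cannot contain any TTAGGG-family rotation
        seq = "".join(np.random.default_rng(1).choice(list("AC"), 300))
        assert find_tmr_arrays(SequenceRecord("c", seq), "TTAGGG") == []

    def test_strand_symmetry(self, rng):
        seq = random_dna(rng, 200) + "TTAGGG" * 8 + random_dna(rng, 150)
        fwd = find_tmr_arrays(SequenceRecord("c", seq), "TTAGGG")
        rev = find_tmr_arrays(SequenceRecord("c", revcomp(seq)), "TTAGGG")
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert (f.copies, f.purity) == (r.copies, r.purity)
        assert f.orientation != r.orientation
        assert (r.start, r.end) == (len(seq) - f.end, len(seq) - f.start)

    def test_purity_invariant_under_rotation_choice(self, rng):
        seq = random_dna(rng, 100) + "TTAGGG" * 6 + random_dna(rng, 100)
        rec = SequenceRecord("c", seq)
        purities = {find_tmr_arrays(rec, m)[0].purity
                    for m in ("TTAGGG", "AGGGTT", "TAACCC")}
        assert len(purities) == 1


class TestMotifOrientation:
    @pytest.mark.parametrize("array_motif,reference,expected", [
        ("CCCTAA", "TTAGGG", "reverse-complement"),
        ("AGGGTT", "TTAGGG", "same"),
        ("TAACCC", "TTAGGG", "reverse-complement"),
    ])
    def test_orientation_cases(self, array_motif, reference, expected):
        arr = find_tmr_arrays(SequenceRecord("c", array_motif * 5),
                              array_motif)[0]
        assert motif_orientation(arr, reference) == expected

    def test_foreign_motif_rejected(self):
        arr = find_tmr_arrays(SequenceRecord("c", "TTAGGG" * 5),
                              "TTAGGG")[0]
        with pytest.raises(ValueError):
            motif_orientation(arr, "ACACAC")

    def test_canonical_motif_family(self):
        assert canonical_motif("TTAGGG") == canonical_motif("TAACCC") \
            == canonical_motif("CCCTAA")


class TestCallJunction:
    def _embedded(self, seed, age=0.0):
        host, tel = build_host(seed=seed, length=5000, motif="TAACCC")
        virus = build_viral_genome(seed=seed + 1)
        site = tel[0] + 60
        genome, truth = embed_viral_insertion(host, virus, site, age,
                                              2.2e-9, seed=seed + 2)
        return genome, truth

    def test_recovers_junction_at_age_zero(self):
        genome, truth = self._embedded(seed=10)
        arrays = find_tmr_arrays(genome, "TAACCC", min_copies=5, max_gap=12)
        s, e = truth.viral_interval
        hits = [_Hit(truth.junction_call_truth + 200, e - 50)]
        host_iv = [(0, truth.integration_site - 60)]
        calls = call_junction(genome, arrays, hits, host_iv)
        assert len(calls) == 1
        assert abs(calls[0].coordinate - truth.junction_call_truth) <= 6

    def test_pure_virus_contig_no_call(self):
        virus = build_viral_genome(seed=3)
        rec = SequenceRecord("v", virus.sequence)
        arrays = find_tmr_arrays(rec, "TAACCC", min_copies=5, max_gap=12)
        # viral hits on both sides of every internal array, no host side
        hits = [_Hit(0, len(rec.seq))]
        assert call_junction(rec, arrays, hits, []) == []

    def test_host_only_contig_no_call(self):
        host, tel = build_host(seed=9, length=3000, motif="TAACCC")
        arrays = find_tmr_arrays(host, "TAACCC", min_copies=5)
        calls = call_junction(host, arrays, [], [(0, tel[0])])
        assert calls == []

    def test_no_array_is_an_error(self, rng):
        rec = SequenceRecord("c", "".join(
            np.random.default_rng(2).choice(list("AC"), 300)))
        with pytest.raises(ValueError):
            call_junction(rec, [], [], [])


class TestTerminalOverlap:
    def test_exact_337_bp_overlap(self, rng):
        a = random_dna(rng, 2000)
        b = a[-337:] + random_dna(rng, 1500)
        ov = terminal_overlap(SequenceRecord("A", a),
                              SequenceRecord("B", b), min_len=100)
        assert (ov.length, ov.mismatches, ov.gaps) == (337, 0, 0)
        assert ov.orientation == "forward"

    def test_one_mismatch_four_gaps(self, rng):
        # the published overlap signature: 337 bp, 1 mismatch, 4 indels
        a = random_dna(rng, 2000)
        seg = list(a[-337:])
        seg[50] = {"A": "C"}.get(seg[50], "A")
        for pos in (300, 240, 170, 100):
            del seg[pos]
        b = "".join(seg) + random_dna(rng, 1500)
        ov = terminal_overlap(SequenceRecord("A", a),
                              SequenceRecord("B", b), min_len=100)
        assert ov.mismatches == 1
        assert ov.gaps == 4
        assert abs(ov.length - 337) <= 4

    def test_reverse_complement_partner_found(self, rng):
        a = random_dna(rng, 1200)
        b = revcomp(a[-250:] + random_dna(rng, 800))
        ov = terminal_overlap(SequenceRecord("A", a),
                              SequenceRecord("B", b), min_len=100)
        assert ov is not None
        assert ov.orientation == "reverse-complement"
        assert ov.length >= 250

    def test_unrelated_contigs_none(self, rng):
        a = random_dna(rng, 1500)
        b = random_dna(rng, 1500)
        assert terminal_overlap(SequenceRecord("A", a),
                                SequenceRecord("B", b),
                                min_len=100) is None

    def test_min_len_floor_enforced(self, rng):
        a = random_dna(rng, 100)
        with pytest.raises(ValueError):
            terminal_overlap(SequenceRecord("A", a),
                             SequenceRecord("B", a), min_len=10)
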