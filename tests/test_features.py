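"""Composition features, PCA behaviour and the permutation outlier test."""

import numpy as np
import pytest

from evescan import (FEATURE_NAMES, FeatureVector, SequenceRecord,
                     contig_features, outlier_assessment, pca,
                     placements_from_truth, simulate_reads)
from tests.conftest import random_dna


def _fv(cid, values):
    return FeatureVector(cid, np.asarray(values, float), True)


def _random_feature_rows(rng, n, shift=None):
    """Rows that respect the frequency-simplex structure of the vector."""
    rows = []
    for i in range(n):
        mono = rng.dirichlet(np.ones(4) * 50)
        di = rng.dirichlet(np.ones(16) * 50)
        if shift is not None:
            di = di + shift
            di = di / di.sum()
        ins = np.sort(rng.normal(300, 15, size=2))
        row = np.concatenate([[rng.uniform(20, 40)], mono, di,
                              [ins.mean(), np.median(ins), ins[0], ins[1]]])
        rows.append(_fv(f"c{i}", row))
    return rows


class TestContigFeatures:
    def test_dinucleotide_counts_aacc(self):
        fv = contig_features(SequenceRecord("c", "AACC"))
        named = dict(zip(FEATURE_NAMES, fv.values))
        assert named["mono_A"] == pytest.approx(0.5)
        assert named["mono_C"] == pytest.approx(0.5)
        assert named["mono_G"] == 0 and named["mono_T"] == 0
        for d in ("AA", "AC", "CC"):
            assert named[f"di_{d}"] == pytest.approx(1 / 3)

    def test_dinucleotide_counts_aatt(self):
        fv = contig_features(SequenceRecord("c", "AATT"))
        named = dict(zip(FEATURE_NAMES, fv.values))
        for d in ("AA", "AT", "TT"):
            assert named[f"di_{d}"] == pytest.approx(1 / 3)

    def test_insert_statistics(self):
        placements = [(0, ins, ins) for ins in range(100, 110)]
        fv = contig_features(SequenceRecord("c", "ACGT" * 100), placements)
        named = dict(zip(FEATURE_NAMES, fv.values))
        assert named["insert_mean"] == pytest.approx(104.5)
        assert named["insert_median"] == pytest.approx(104.5)
        assert (named["insert_min"], named["insert_max"]) == (100, 109)

    def test_no_placements_null_flagged(self):
        fv = contig_features(SequenceRecord("c", "ACGT" * 10))
        assert not fv.has_inserts
        assert np.isnan(fv.values[-4:]).all()
        assert fv.values[0] == 0.0

    def test_feature_names_stable(self):
        assert FEATURE_NAMES[0] == "coverage"
        assert len(FEATURE_NAMES) == len(set(FEATURE_NAMES))
        assert FEATURE_NAMES[-4:] == ("insert_mean", "insert_median",
                                      "insert_min", "insert_max")

    def test_truth_placements_give_positive_coverage(self, rng):
        genome = SequenceRecord("g", random_dna(rng, 4000))
        pairs = simulate_reads(genome, coverage=10, seed=2)
        placements = placements_from_truth((500, 3500), pairs)
        fv = contig_features(
            SequenceRecord("c", genome.seq[500:3500]), placements)
        assert fv.values[0] > 0
        assert fv.has_inserts


class TestPCA:
    def test_rank_two_matrix_explained_by_two_components(self, rng):
        # constant frequency blocks; the varying features (coverage and
        # insert statistics) are exact linear functions of 2 latent factors
        rows = []
        for i in range(40):
            a, b = rng.normal(size=2)
            v = np.concatenate([
                [30 + a], np.full(4, 0.25), np.full(16, 1 / 16),
                [300 + 2 * a - b, 300 + a + b, 200.0, 400.0]])
            rows.append(FeatureVector(f"c{i}", v, True))
        res = pca(rows, standardize=False)
        assert res.explained[:2].sum() == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, rng):
        res = pca(_random_feature_rows(rng, 30))
        assert res.explained.sum() == pytest.approx(1.0)

    def test_duplicating_rows_leaves_loadings_unchanged(self, rng):
        rows = _random_feature_rows(rng, 25)
        dup = rows + [FeatureVector(f.contig_id + "_dup", f.values.copy(),
                                    True) for f in rows]
        a = pca(rows)
        b = pca(dup)
        for j in range(2):
            ca = a.loadings[:, j]
            cb = b.loadings[:, j]
            assert min(np.abs(ca - cb).max(),
                       np.abs(ca + cb).max()) < 1e-8

    def test_null_flagged_rows_excluded(self, rng):
        rows = _random_feature_rows(rng, 10)
        rows.append(contig_features(SequenceRecord("empty", "ACGT" * 50)))
        res = pca(rows)
        assert res.excluded_ids == ["empty"]
        assert "empty" not in res.scores.index

    def test_identical_rows_zero_variance_error(self):
        v = np.concatenate([[10.0], np.full(4, 0.25), np.full(16, 1 / 16),
                            [300, 300, 280, 320]])
        rows = [FeatureVector(f"c{i}", v.copy(), True) for i in range(5)]
        with pytest.raises(ValueError, match="variance"):
            pca(rows)


class TestOutlierAssessment:
    def test_single_flagged_contig_distance_only(self, rng):
        res = pca(_random_feature_rows(rng, 20))
        rep = outlier_assessment(res, ["c3"], seed=1)
        assert rep.p_value is None
        assert rep.centroid_distance >= 0

    def test_shifted_group_detected(self, rng):
        bulk = _random_feature_rows(rng, 60)
        shifted = _random_feature_rows(rng, 6, shift=np.linspace(
            0.03, -0.03, 16))
        for i, f in enumerate(shifted):
            f.contig_id = f"v{i}"
        res = pca(bulk + shifted)
        rep = outlier_assessment(res, [f"v{i}" for i in range(6)],
                                 n_permutations=499, seed=2)
        assert rep.p_value < 0.05

    def test_null_group_p_not_extreme(self, rng):
        # a bulk-drawn flagged group should not look clustered
        rows = _random_feature_rows(rng, 60)
        res = pca(rows)
        ps = []
        for s in range(20):
            flagged = [f"c{i}" for i in
                       np.random.default_rng(s).choice(60, 6,
                                                       replace=False)]
            ps.append(outlier_assessment(res, flagged, n_permutations=199,
                                         seed=s).p_value)
        # uniform-ish: not all small
        assert np.mean(np.array(ps) < 0.05) < 0.3

    def test_unknown_flagged_id_rejected(self, rng):
        res = pca(_random_feature_rows(rng, 10))
        with pytest.raises(ValueError):
            outlier_assessment(res, ["nope"])

    def test_seed_reproducibility(self, rng):
        res = pca(_random_feature_rows(rng, 30))
        a = outlier_assessment(res, ["c1", "c2", "c3"], seed=7)
        b = outlier_assessment(res, ["c1", "c2", "c3"], seed=7)
        assert a.p_value == b.p_value
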