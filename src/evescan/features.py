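"""Per-contig composition/coverage features and PCA outlier assessment.

Each contig is summarised by 25 variables: mean read coverage depth, the
four mononucleotide and sixteen dinucleotide frequencies, and the mean,
median, minimum and maximum insert size of its properly paired reads.
A PCA over standardized features shows whether candidate viral contigs are
compositional outliers relative to the assembly bulk; a label-permutation
test on the first two principal components turns the qualitative
"viral contigs cluster together" observation into a seedable statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .records import SequenceRecord

MONO = tuple("ACGT")
DI = tuple("".join(p) for p in itertools.product("ACGT", repeat=2))

FEATURE_NAMES = (
    ("coverage",)
    + tuple(f"mono_{b}" for b in MONO)
    + tuple(f"di_{d}" for d in DI)
    + ("insert_mean", "insert_median", "insert_min", "insert_max")
)
N_FEATURES = len(FEATURE_NAMES)  # 25


@dataclass
class FeatureVector:
    contig_id: str
    values: np.ndarray           # aligned with FEATURE_NAMES
    has_inserts: bool            # False: insert fields are null-flagged

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} feature values")
        mono = self.values[1:5]
        di = self.values[5:21]
        if mono.sum() > 0 and not np.isclose(mono.sum(), 1.0):
            raise ValueError("mononucleotide frequencies must sum to 1")
        if di.sum() > 0 and not np.isclose(di.sum(), 1.0):
            raise ValueError("dinucleotide frequencies must sum to 1")
        if self.has_inserts and self.values[23] > self.values[24]:
            raise ValueError("insert min exceeds max")


def contig_features(contig: SequenceRecord, placements=None) -> FeatureVector:
    """Compute the per-contig feature vector (coverage, composition, inserts).

    ``placements`` is an iterable of (start, end, insert_size) tuples for
    properly paired reads on the contig (forward coordinates, half-open
    fragment span clipped to the contig).  With no placements, coverage is
    0 and the insert fields are NaN (null-flagged).
    """
    if len(contig.seq) < 2:
        raise ValueError("contig shorter than 2 nt")
    seq = contig.seq
    n = len(seq)
    mono_counts = {b: seq.count(b) for b in MONO}
    mono_total = sum(mono_counts.values())  # N excluded
    di_counts = dict.fromkeys(DI, 0)
    for i in range(n - 1):
        d = seq[i:i + 2]
        if d in di_counts:
            di_counts[d] += 1
    di_total = sum(di_counts.values())

    vals = [0.0]
    vals += [mono_counts[b] / mono_total if mono_total else 0.0
             for b in MONO]
    vals += [di_counts[d] / di_total if di_total else 0.0 for d in DI]

    placements = list(placements or [])
    if placements:
        aligned = sum(min(e, n) - max(s, 0) for s, e, _ in placements)
        inserts = np.array([ins for _, _, ins in placements], float)
        vals[0] = aligned / n
        vals += [float(inserts.mean()), float(np.median(inserts)),
                 float(inserts.min()), float(inserts.max())]
        has = True
    else:
        vals += [np.nan] * 4
        has = False
    return FeatureVector(contig.id, np.array(vals), has)


def placements_from_truth(contig_interval, pairs):
    """Truth-channel read placements for a contig that is a genome slice.

    ``contig_interval`` is the (start, end) of the contig on the simulated
    genome; pairs whose fragment lies entirely within it become
    (start, end, insert) placements in contig coordinates.
    """
    s0, e0 = contig_interval
    out = []
    for p in pairs:
        s, e = p.origin
        if s >= s0 and e <= e0:
            out.append((s - s0, e - s0, p.insert_size))
    return out


@dataclass
class PCAResult:
    loadings: np.ndarray          # n_features x n_components
    scores: pd.DataFrame          # contig id index, PC columns
    explained: np.ndarray         # variance fractions, sum to 1
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    excluded_ids: list


def pca(features: list[FeatureVector], standardize: bool = True) -> PCAResult:
    """PCA over complete feature rows (null-flagged rows excluded)."""
    complete = [f for f in features if np.all(np.isfinite(f.values))]
    excluded = [f.contig_id for f in features
                if not np.all(np.isfinite(f.values))]
    if len(complete) < 2:
        raise ValueError("need at least 2 complete feature rows")
    X = np.vstack([f.values for f in complete])
    keep = X.std(axis=0) > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant features (zero variance)")
    mean = X.mean(axis=0)
    sd = np.where(keep, X.std(axis=0, ddof=1), 1.0)
    Xw = X[:, keep] - mean[keep]
    if standardize:
        Xw = Xw / sd[keep]
    model = _SKPCA()
    scores = model.fit_transform(Xw)
    loadings = np.zeros((X.shape[1], model.components_.shape[0]))
    loadings[keep, :] = model.components_.T
    expl = model.explained_variance_ratio_
    idx = [f.contig_id for f in complete]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        loadings=loadings,
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        explained=expl,
        feature_mean=mean, feature_sd=sd, excluded_ids=excluded,
    )


@dataclass
class OutlierReport:
    flagged_ids: list
    centroid_distance: float      # flagged centroid vs bulk centroid, PC1-2
    p_value: float | None         # None for a distance-only report
    n_permutations: int


def outlier_assessment(result: PCAResult, flagged_ids: list,
                       n_permutations: int = 999,
                       seed: int | None = None) -> OutlierReport:
    """Permutation test of flagged-group cohesion on the first two PCs.

    The statistic is the distance between the flagged-group centroid and
    the overall centroid; the null permutes the flag labels.  With a single
    flagged contig only the distance is reported.
    """
    missing = set(flagged_ids) - set(result.scores.index)
    if missing:
        raise ValueError(f"flagged ids not scored: {sorted(missing)}")
    pcs = result.scores.iloc[:, :2].to_numpy()
    ids = list(result.scores.index)
    mask = np.array([i in set(flagged_ids) for i in ids])
    centroid_all = pcs.mean(axis=0)
    stat = float(np.linalg.norm(pcs[mask].mean(axis=0) - centroid_all))
    if mask.sum() < 2:
        return OutlierReport(list(flagged_ids), stat, None, 0)
    rng = np.random.default_rng(seed)
    k = int(mask.sum())
    count = 0
    for _ in range(n_permutations):
        perm = rng.choice(len(ids), size=k, replace=False)
        s = float(np.linalg.norm(pcs[perm].mean(axis=0) - centroid_all))
        if s >= stat:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return OutlierReport(list(flagged_ids), stat, p, n_permutations)


def features_to_tsv(features: list[FeatureVector], path) -> None:
    df = pd.DataFrame(
        [f.values for f in features],
        index=[f.contig_id for f in features],
        columns=list(FEATURE_NAMES),
    )
    df.index.name = "contig"
    df.to_csv(path, sep="\t")
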