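"""Dating an endogenous insertion from telomeric-repeat divergence.

At integration time the terminus-facing telomeric array of the viral direct
repeat is assumed to have been a perfect tandem of the hexamer motif; every
departure from that structure accumulated neutrally afterwards.  The
observed array window (anchored at intact motif copies on both ends) is
therefore compared with a hypothetical perfect-repeat ancestor, the
maximum-likelihood pairwise distance d is estimated under the general
time-reversible (GTR) model, and the age follows as t = d / r for a neutral
rate r — without halving, because the divergence spans a single lineage
from a known ancestral state, not two contemporary lineages.

The likelihood is that of independent paired sites with a KNOWN ancestor:
for ancestor base i and observed base j the site contributes
log [exp(Q d)]_{ij}, i.e. the ancestor states are conditioned on rather
than drawn from the stationary distribution — a perfect hexamer repeat is
nothing like a stationary GTR sample (the TAACCC ancestor contains no G at
all), and the unconditional pi_i * P_ij likelihood is badly misspecified
for it.  For the same reason the generator is normalised to one expected
substitution per site under the ANCESTOR base composition, so d means
"expected substitutions accumulated per ancestral site", the quantity a
known-ancestor divergence measures.  The fit maximises over d, the six
exchangeabilities and the frequency parameters of Q; when optimisation
fails, a log-det estimate is the fallback, and when the empirical
divergence matrix is singular even for that, the data are declared
saturated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .records import SequenceRecord
from .synthetic import BASES
from .junctions import TMRArray, find_tmr_arrays

_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: neutral substitution rates reported side by side (subs/site/year):
#: a general mammalian rate and a bushbaby (small prosimian) rate
DEFAULT_RATES = (2.2e-9, 3e-9)

NON_NEUTRAL_WARNING = (
    "telomeric-repeat arrays may evolve under a non-neutral pattern and "
    "rate of substitution; treat the age as approximate"
)


@dataclass
class PerfectRepeatModel:
    """Hypothetical perfect-repeat ancestor of an observed array."""

    motif: str
    copies: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence.startswith(self.motif * (len(self.sequence)
                                                      // len(self.motif))):
            raise ValueError("sequence is not a tiling of the motif")


def build_perfect_repeat(motif: str, length: int,
                         allow_truncation: bool = True) -> PerfectRepeatModel:
    """Tile a motif to the requested length (phase-aligned truncation)."""
    if length < len(motif):
        raise ValueError("length must be at least one motif copy")
    if length % len(motif) and not allow_truncation:
        raise ValueError("length not divisible by motif length")
    reps = -(-length // len(motif))
    return PerfectRepeatModel(motif, length // len(motif),
                              (motif * reps)[:length])


def extract_anchored_window(array_seq: str, motif: str) -> str:
    """Maximal subsequence from the first to the last intact motif copy.

    Internal degraded copies are retained; the window begins at the start
    of the first exact occurrence of ``motif`` and ends at the end of the
    last.  Requires at least two intact copies.
    """
    first = array_seq.find(motif)
    last = array_seq.rfind(motif)
    if first < 0 or last <= first:
        raise ValueError("fewer than 2 intact motif copies in array")
    return array_seq[first:last + len(motif)]


@dataclass
class SitePairCounts:
    """4x4 (ancestor base, observed base) counts — the distance statistic."""

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        if self.counts.shape != (4, 4) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 4x4 matrix")
        if not np.isclose(self.counts.sum(), self.total):
            raise ValueError("total does not match counts sum")


def _global_dna_aligner():
    from Bio.Align import PairwiseAligner

    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -1
    a.open_gap_score = -6
    a.extend_gap_score = -1
    return a


def pair_sites(observed: str, ancestor: PerfectRepeatModel,
               min_sites: int = 50) -> SitePairCounts:
    """Aligned (ancestor, observed) base-pair counts.

    Equal lengths pair positionally; unequal lengths trigger a global
    affine-gap alignment with gap columns excluded.
    """
    anc = ancestor.sequence
    counts = np.zeros((4, 4))
    if len(observed) == len(anc):
        pairs = zip(anc, observed)
        for x, y in pairs:
            if x in _BASE_IDX and y in _BASE_IDX:
                counts[_BASE_IDX[x], _BASE_IDX[y]] += 1
    else:
        aln = _global_dna_aligner().align(anc, observed)[0]
        ta, qa = aln.aligned[0], aln.aligned[1]
        for k in range(len(ta)):
            for x, y in zip(anc[ta[k][0]:ta[k][1]],
                            observed[qa[k][0]:qa[k][1]]):
                if x in _BASE_IDX and y in _BASE_IDX:
                    counts[_BASE_IDX[x], _BASE_IDX[y]] += 1
    total = int(counts.sum())
    if total < min_sites:
        raise ValueError(
            f"only {total} paired sites (< {min_sites}); distance unreliable"
        )
    return SitePairCounts(counts, total)


@dataclass
class GTRDistanceEstimate:
    """ML pairwise distance with the fitted GTR parameters."""

    d: float
    exchangeabilities: np.ndarray
    freqs: np.ndarray
    log_likelihood: float
    estimator: str = "ML"   # 'ML' | 'logdet-fallback'

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("distance must be non-negative")


_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def _gtr_probability(d: float, exch: np.ndarray, freqs: np.ndarray,
                     norm_weights: np.ndarray | None = None) -> np.ndarray:
    """P(d) = exp(Q d) with Q scaled to unit rate under ``norm_weights``.

    ``norm_weights`` defaults to the stationary frequencies; for a
    known-ancestor branch it should be the ancestor base composition.
    Computed by eigendecomposition of the pi-symmetrised generator.
    """
    s = np.zeros((4, 4))
    for k, (i, j) in enumerate(_PAIRS):
        s[i, j] = s[j, i] = exch[k]
    q = s * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    w = freqs if norm_weights is None else norm_weights
    mu = -(w * np.diag(q)).sum()
    if not mu > 0:
        raise ValueError("degenerate generator")
    q = q / mu
    sp = np.sqrt(np.clip(freqs, 1e-12, None))
    b = (sp[:, None] * q) / sp[None, :]
    b = 0.5 * (b + b.T)
    lam, vec = np.linalg.eigh(b)
    p = (vec * np.exp(lam * d)) @ vec.T
    p = p / sp[:, None] * sp[None, :]
    return np.clip(p, 1e-300, None)


def _logdet_distance(counts: np.ndarray) -> float:
    """Log-det (paralinear) distance; raises on a singular matrix."""
    F = counts / counts.sum()
    detF = np.linalg.det(F)
    if detF <= 0:
        raise ValueError("saturation: divergence matrix is singular")
    fa = F.sum(axis=1)
    fb = F.sum(axis=0)
    if np.any(fa <= 0) or np.any(fb <= 0):
        raise ValueError("saturation: missing base in one sequence")
    return float(-0.25 * (math.log(detF)
                          - 0.5 * (np.log(fa).sum() + np.log(fb).sum())))


def estimate_gtr_distance(counts: SitePairCounts,
                          min_sites: int = 50) -> GTRDistanceEstimate:
    """Maximum-likelihood GTR distance from known-ancestor paired counts.

    Maximises the conditional likelihood sum_ij N_ij log P_ij(d) over d,
    five free exchangeabilities (GT = 1) and the frequency parameters of
    the generator, with the generator normalised to unit rate under the
    ancestor base composition.  Falls back to the log-det (paralinear)
    estimator when the optimisation fails; a singular divergence matrix in
    the fallback raises a saturation error.
    """
    N = counts.counts
    if counts.total < min_sites:
        raise ValueError(f"fewer than {min_sites} paired sites")
    off = N.sum() - np.trace(N)
    anc_comp = N.sum(axis=1) / N.sum()
    if off == 0:
        return GTRDistanceEstimate(0.0, np.ones(6), anc_comp,
                                   log_likelihood=0.0)

    p = off / N.sum()
    mask = N > 0

    # Jukes-Cantor member of the family: closed-form MLE and its
    # conditional log-likelihood, used both as the optimisation start and
    # as the null in nested-model selection (AIC) against the full GTR fit
    jc = None
    if p < 0.7499:
        d_jc = -0.75 * math.log(1 - 4 * p / 3)
        p_model = 0.75 * (1 - math.exp(-4 * d_jc / 3))
        ll_jc = float((N.sum() - off) * math.log(max(1 - p_model, 1e-300))
                      + off * math.log(max(p_model / 3, 1e-300)))
        jc = (d_jc, ll_jc)
        d0 = d_jc
    else:
        d0 = 1.5

    def nll(theta):
        theta = np.clip(theta, -12.0, 12.0)
        d = math.exp(theta[0])
        exch = np.exp(np.append(theta[1:6], 0.0))
        logits = np.append(theta[6:9], 0.0)
        pi = np.exp(logits - logits.max())
        pi = np.clip(pi / pi.sum(), 1e-8, None)
        pi = pi / pi.sum()
        try:
            P = _gtr_probability(d, exch, pi, norm_weights=anc_comp)
        except (ValueError, FloatingPointError):
            return 1e12
        val = -float((N[mask] * np.log(P[mask])).sum())
        return val if np.isfinite(val) else 1e12

    x0 = np.concatenate([[math.log(max(d0, 1e-4))], np.zeros(8)])
    best = None
    with np.errstate(over="ignore", invalid="ignore"):
        for method, opts in (("L-BFGS-B", {"maxiter": 300}),
                             ("Nelder-Mead", {"xatol": 1e-6,
                                              "fatol": 1e-9,
                                              "maxfev": 6000})):
            try:
                res = minimize(nll, x0, method=method, options=opts)
            except Exception:
                continue
            if res.fun < 1e11 and (best is None or res.fun < best.fun):
                best = res
            if best is not None and method == "L-BFGS-B":
                break
    # prefer the 1-parameter JC member unless the 9-parameter GTR fit
    # earns its extra parameters (AIC: delta logL > 8)
    if jc is not None and (best is None or (-best.fun) - jc[1] <= 8.0):
        return GTRDistanceEstimate(jc[0], np.ones(6), np.full(4, 0.25),
                                   log_likelihood=jc[1], estimator="ML")
    if best is not None:
        theta = np.clip(best.x, -12.0, 12.0)
        exch = np.exp(np.append(theta[1:6], 0.0))
        logits = np.append(theta[6:9], 0.0)
        pi = np.exp(logits - logits.max())
        pi = pi / pi.sum()
        return GTRDistanceEstimate(math.exp(theta[0]), exch, pi,
                                   log_likelihood=-best.fun,
                                   estimator="ML")
    d_hat = _logdet_distance(N)  # raises "saturation" when singular
    return GTRDistanceEstimate(max(d_hat, 0.0), np.ones(6), anc_comp,
                               log_likelihood=float("nan"),
                               estimator="logdet-fallback")


@dataclass
class AgeEstimate:
    """Age of an insertion from divergence d and neutral rate r.

    t = d / r exactly; the divergence spans one lineage from a known
    ancestral state, so it is never halved (``halved`` records misuse of
    the pairwise escape hatch and must be False for a valid age).
    """

    d: float
    rate: float
    t_years: float
    halved: bool = False
    warning: str = NON_NEUTRAL_WARNING

    def __post_init__(self) -> None:
        expected = (self.d / self.rate) / (2.0 if self.halved else 1.0)
        if not math.isclose(self.t_years, expected, rel_tol=1e-12,
                            abs_tol=1e-9):
            raise ValueError("t must equal d / rate (no halving)")


def distance_to_age(d: float, rate: float,
                    pairwise: bool = False) -> AgeEstimate:
    """Convert a divergence to years: t = d / rate, never halved by default.

    ``pairwise=True`` is an escape hatch that halves the distance as for
    two contemporary lineages and flags the estimate, so misuse is visible.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    t = d / rate / (2.0 if pairwise else 1.0)
    return AgeEstimate(d=d, rate=rate, t_years=t, halved=pairwise)


@dataclass
class DatingReport:
    contig_id: str
    array: TMRArray
    window_length: int
    distance: GTRDistanceEstimate
    ages: list  # AgeEstimate per rate


def date_integration(
    contig: SequenceRecord,
    motif: str = "TAACCC",
    rates=DEFAULT_RATES,
    min_copies: int = 3,
    max_gap: int = 48,
    region: tuple[int, int] | None = None,
) -> DatingReport:
    """End-to-end dating of the insertion carried by a contig.

    Detects telomeric arrays, selects the one with the longest anchored
    window, compares it with a perfect-repeat ancestor and converts the ML
    distance to an age per supplied rate.  ``max_gap`` defaults to eight
    motif units: at the divergences this tool dates, intact copies of a
    heavily degraded array can sit tens of bases apart, and a small gap
    ceiling would fragment the array into its least-diverged islands and
    bias the distance downwards.

    ``region`` restricts the search to a sub-interval of the contig — the
    junction-mediating array fuses the host telomere with the viral
    terminal repeat, and only the viral-side portion dates the insertion,
    so the caller passes the viral side of a junction call here.
    """
    if region is not None:
        lo, hi = max(0, region[0]), min(len(contig.seq), region[1])
        contig = SequenceRecord(contig.id, contig.seq[lo:hi], "dna")
    arrays = find_tmr_arrays(contig, motif=motif, min_copies=min_copies,
                             max_gap=max_gap)
    if not arrays:
        raise ValueError(f"stage find_tmr_arrays: no datable array on "
                         f"{contig.id}")
    best = None
    for arr in arrays:
        try:
            window = extract_anchored_window(
                contig.seq[arr.start:arr.end], motif)
        except ValueError:
            continue
        if best is None or len(window) > len(best[1]):
            best = (arr, window)
    if best is None:
        raise ValueError("stage extract_anchored_window: no array with 2 "
                         "intact motif copies")
    arr, window = best
    ancestor = build_perfect_repeat(motif, len(window))
    try:
        counts = pair_sites(window, ancestor)
    except ValueError as e:
        raise ValueError(f"stage pair_sites: {e}") from e
    try:
        dist = estimate_gtr_distance(counts)
    except ValueError as e:
        raise ValueError(f"stage estimate_gtr_distance: {e}") from e
    ages = [distance_to_age(dist.d, r) for r in rates]
    return DatingReport(contig.id, arr, len(window), dist, ages)
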