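"""Translated homology discovery: consensus queries, six-frame search,
shortlist filtering and reciprocal best-hit classification.

The search follows the tBLASTn idiom: a protein query is aligned locally
(Smith-Waterman semantics, BLOSUM62, affine gaps) against all six reading
frames of each contig; significance uses Karlin-Altschul statistics
E = K * m * n * exp(-lambda * S) with n the total translated search-space
length.  Per frame, non-overlapping locally optimal alignments are
enumerated by iterative masking of the best hit.  BLAST seeding heuristics
are deliberately not reproduced: candidate regions at desk scale are small
enough for exact local alignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .records import SequenceRecord, revcomp

FRAMES = (1, 2, 3, -1, -2, -3)

#: ungapped Karlin-Altschul parameters for BLOSUM62
KA_LAMBDA = 0.3176
KA_K = 0.134


@dataclass
class ConsensusQuery:
    cluster_id: str
    residues: str
    support: list  # per-column fraction of non-gap rows agreeing

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty consensus")
        if any(not (0.0 <= f <= 1.0) for f in self.support):
            raise ValueError("support fractions must lie in [0,1]")


@dataclass
class ScoringScheme:
    """Substitution matrix, gap penalties and E-value statistics."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    ka_lambda: float = KA_LAMBDA
    ka_k: float = KA_K

    def __post_init__(self) -> None:
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        self.matrix = substitution_matrices.load(self.matrix_name)

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.ka_k * m * n * math.exp(-self.ka_lambda * score)

    def bitscore(self, score: float) -> float:
        return (self.ka_lambda * score - math.log(self.ka_k)) / math.log(2)


@dataclass
class TranslatedHit:
    """One local alignment between a protein query and a translated frame."""

    query_id: str
    subject_id: str
    frame: int
    subject_start: int   # forward-strand nt coords, 0-based half-open
    subject_end: int
    query_start: int     # aa coords on the query, 0-based half-open
    query_end: int
    length: int          # alignment columns (aa, gaps included)
    identities: int
    mismatches: int
    gap_opens: int
    score: float
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")

    @property
    def pident(self) -> float:
        return 100.0 * self.identities / self.length


@dataclass
class FilterPolicy:
    """Shortlist filter: minimum hit length and E-value significance.

    ``discard_significant`` flips the E-value direction for users who want
    the literal (inverted) reading of the published filter phrase; the
    default keeps significant hits (E <= max_evalue).
    """

    min_length: int = 50
    max_evalue: float = 1e-10
    discard_significant: bool = False

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


def build_consensus(alignment: list[SequenceRecord], threshold: float = 0.5,
                    cluster_id: str | None = None) -> ConsensusQuery:
    """Plurality consensus of an aligned protein cluster.

    Per column, the most frequent residue among non-gap rows is emitted when
    its fraction reaches ``threshold``; otherwise 'X'.  All-gap columns are
    dropped.
    """
    if not alignment:
        raise ValueError("empty alignment")
    if not (0.5 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0.5, 1]")
    ncol = len(alignment[0].seq)
    if any(len(r.seq) != ncol for r in alignment):
        raise ValueError("alignment rows differ in length")
    out = []
    support = []
    for j in range(ncol):
        col = [r.seq[j] for r in alignment if r.seq[j] not in "-."]
        if not col:
            continue
        vals, counts = np.unique(col, return_counts=True)
        best = counts.max()
        frac = best / len(col)
        winners = vals[counts == best]
        if frac >= threshold and len(winners) == 1:
            out.append(str(winners[0]))
            support.append(float(frac))
        else:
            out.append("X")
            support.append(float(frac))
    return ConsensusQuery(cluster_id or alignment[0].id, "".join(out), support)


def six_frame_translate(dna: SequenceRecord) -> dict[int, str]:
    """Standard-code translation of all six frames.

    Frames +1..+3 read the forward strand, -1..-3 the reverse complement.
    Stops are rendered '*'; codons containing N translate to 'X'; trailing
    partial codons are dropped.
    """
    if dna.alphabet != "dna":
        raise ValueError("six_frame_translate expects DNA")
    if len(dna.seq) < 3:
        raise ValueError("sequence shorter than one codon")
    frames = {}
    rc = revcomp(dna.seq)
    for f in (1, 2, 3):
        for strand_seq, sign in ((dna.seq, 1), (rc, -1)):
            sub = strand_seq[f - 1:]
            sub = sub[: 3 * (len(sub) // 3)]
            frames[sign * f] = str(Seq(sub).translate()) if sub else ""
    return frames


def _frame_to_forward(frame: int, aa_start: int, aa_end: int,
                      contig_len: int) -> tuple[int, int]:
    """Map an aa interval in a frame to forward-strand nt coordinates."""
    off = abs(frame) - 1
    s = off + 3 * aa_start
    e = off + 3 * aa_end
    if frame > 0:
        return s, e
    return contig_len - e, contig_len - s


def _make_aligner(scoring: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scoring.matrix
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def translated_search(
    query: ConsensusQuery | SequenceRecord,
    contigs: list[SequenceRecord],
    scoring: ScoringScheme | None = None,
    min_raw_score: float = 30.0,
    max_hits_per_frame: int = 5,
) -> list[TranslatedHit]:
    """Search a protein query against six-frame translations of contigs.

    Returns hits sorted by E-value.  Per frame, up to ``max_hits_per_frame``
    non-overlapping locally optimal alignments are found by masking each
    best hit with 'X' and re-aligning.
    """
    if scoring is None:
        scoring = ScoringScheme()
    qseq = query.residues if isinstance(query, ConsensusQuery) else query.seq
    qid = query.cluster_id if isinstance(query, ConsensusQuery) else query.id
    if not qseq:
        raise ValueError("empty query")
    aligner = _make_aligner(scoring)

    translations = []
    for contig in contigs:
        if len(contig.seq) < 3:
            warnings.warn(f"contig {contig.id} shorter than 3 nt; skipped")
            continue
        translations.append((contig, six_frame_translate(contig)))
    space_n = sum(
        len(t) for _, frames in translations for t in frames.values()
    )
    m = len(qseq)

    hits = []
    for contig, frames in translations:
        for frame in FRAMES:
            prot = frames[frame]
            if not prot:
                continue
            masked = prot
            for _ in range(max_hits_per_frame):
                alns = aligner.align(qseq, masked)
                if alns.score < max(min_raw_score, 1e-9):
                    break
                aln = alns[0]
                (q0, q1, s0, s1, cols, ident, gapo) = _alignment_stats(aln)
                score = float(alns.score)
                nt0, nt1 = _frame_to_forward(frame, s0, s1, len(contig.seq))
                hits.append(TranslatedHit(
                    query_id=qid, subject_id=contig.id, frame=frame,
                    subject_start=nt0, subject_end=nt1,
                    query_start=q0, query_end=q1,
                    length=cols, identities=ident,
                    mismatches=cols - ident - _gap_cols(aln),
                    gap_opens=gapo, score=score,
                    bitscore=scoring.bitscore(score),
                    evalue=scoring.evalue(score, m, space_n),
                ))
                masked = masked[:s0] + "X" * (s1 - s0) + masked[s1:]
    hits.sort(key=lambda h: (h.evalue, -h.score))
    return hits


def _alignment_stats(aln):
    """(q_start, q_end, s_start, s_end, columns, identities, gap_opens)
    for an alignment produced as aligner.align(query, subject)."""
    qa, sa = aln.aligned[0], aln.aligned[1]
    q_start, q_end = int(qa[0][0]), int(qa[-1][1])
    s_start, s_end = int(sa[0][0]), int(sa[-1][1])
    cols = 0
    ident = 0
    gap_opens = 0
    qstr = str(aln.sequences[0])
    sstr = str(aln.sequences[1])
    for k in range(len(qa)):
        a0, a1 = qa[k]
        b0, b1 = sa[k]
        cols += a1 - a0
        for x, y in zip(qstr[a0:a1], sstr[b0:b1]):
            if x == y:
                ident += 1
        if k:
            gap = max(qa[k][0] - qa[k - 1][1], sa[k][0] - sa[k - 1][1])
            if gap > 0:
                gap_opens += 1
                cols += gap
    return q_start, q_end, s_start, s_end, cols, ident, gap_opens


def _gap_cols(aln) -> int:
    qa, sa = aln.aligned[0], aln.aligned[1]
    gaps = 0
    for k in range(1, len(qa)):
        gaps += max(qa[k][0] - qa[k - 1][1], sa[k][0] - sa[k - 1][1])
    return gaps


def shortlist_hits(hits: list[TranslatedHit],
                   policy: FilterPolicy | None = None) -> list[TranslatedHit]:
    """Apply the length and E-value shortlist filter."""
    if policy is None:
        policy = FilterPolicy()
    out = []
    for h in hits:
        if h.length < policy.min_length:
            continue
        significant = h.evalue <= policy.max_evalue
        if policy.discard_significant:
            if not significant:
                out.append(h)
        elif significant:
            out.append(h)
    return out


@dataclass
class ReciprocalCall:
    """Reciprocal best-hit verdict for a candidate viral region."""

    region_id: str
    best_viral: tuple | None       # (protein id, bit score)
    best_non_viral: tuple | None
    verdict: str                   # viral | false-positive | ambiguous

    def __post_init__(self) -> None:
        if self.verdict not in ("viral", "false-positive", "ambiguous"):
            raise ValueError(f"bad verdict {self.verdict!r}")


def reciprocal_classify(
    region: SequenceRecord,
    viral_proteins: list[SequenceRecord],
    non_viral_proteins: list[SequenceRecord],
    scoring: ScoringScheme | None = None,
    min_raw_score: float = 30.0,
) -> ReciprocalCall:
    """Classify a contig region by best viral vs best non-viral match.

    The region's six frames are searched against both protein sets; the
    verdict is 'viral' when the best viral bit score strictly exceeds the
    best non-viral one, 'false-positive' when reversed, and 'ambiguous' on
    an exact tie (or when neither set hits).
    """
    if not viral_proteins or not non_viral_proteins:
        raise ValueError("both protein databases must be non-empty")
    if scoring is None:
        scoring = ScoringScheme()

    def best(db):
        top = None
        for prot in db:
            hits = translated_search(prot, [region], scoring,
                                     min_raw_score=min_raw_score,
                                     max_hits_per_frame=1)
            if hits and (top is None or hits[0].bitscore > top[1]):
                top = (prot.id, hits[0].bitscore)
        return top

    bv, bn = best(viral_proteins), best(non_viral_proteins)
    if bv is None and bn is None:
        verdict = "ambiguous"
    elif bn is None or (bv is not None and bv[1] > bn[1]):
        verdict = "viral"
    elif bv is None or bn[1] > bv[1]:
        verdict = "false-positive"
    else:
        verdict = "ambiguous"
    return ReciprocalCall(region.id, bv, bn, verdict)


def hits_to_tsv(hits: list[TranslatedHit], path) -> None:
    """Export hits in BLAST outfmt-6 style plus a frame column."""
    import pandas as pd

    rows = [{
        "qseqid": h.query_id, "sseqid": h.subject_id,
        "pident": round(h.pident, 3), "length": h.length,
        "mismatch": h.mismatches, "gapopen": h.gap_opens,
        "qstart": h.query_start + 1, "qend": h.query_end,
        "sstart": h.subject_start + 1, "send": h.subject_end,
        "evalue": h.evalue, "bitscore": round(h.bitscore, 1),
        "frame": h.frame,
    } for h in hits]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
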