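"""Telomeric-repeat arrays, host/virus junction calls and terminal overlaps.

Telomeric hexamer repeats (the TTAGGG family) are detected up to rotation
and strand: the canonical representative of a motif is the
lexicographically smallest string over the six rotations of both strands,
so TTAGGG, ATTGGG and TAACCC all name the same repeat family.  Orientation
is defined per strand only — rotations of a motif share an orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner

from .records import SequenceRecord, revcomp


def rotations(motif: str) -> set[str]:
    return {motif[i:] + motif[:i] for i in range(len(motif))}


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation over both strands."""
    return min(rotations(motif) | rotations(revcomp(motif)))


@dataclass
class TMRArray:
    """A detected telomeric-repeat array."""

    contig_id: str
    start: int
    end: int
    motif: str           # canonical representative of the family
    orientation: str     # 'same' | 'reverse-complement' w.r.t. query_motif
    copies: int          # intact hexamer copies found
    purity: float        # intact copies / hexamer windows in the interval
    query_motif: str = ""  # motif string used at detection time

    def __post_init__(self) -> None:
        if self.end - self.start < 12:
            raise ValueError("array must span at least two hexamer copies")
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must lie in [0,1]")
        if len(self.motif) != 6:
            raise ValueError("motif must be a hexamer")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def find_tmr_arrays(
    contig: SequenceRecord,
    motif: str = "TTAGGG",
    min_copies: int = 3,
    max_gap: int = 6,
) -> list[TMRArray]:
    """Maximal runs of hexamer-motif copies (any rotation, either strand).

    Copies are exact occurrences of any rotation of the motif or of its
    reverse complement, tiled greedily left to right; consecutive copies
    whose spacing exceeds ``max_gap`` start a new array.  Purity is the
    number of intact copies over the number of hexamer windows spanned by
    the array interval.
    """
    if len(motif) != 6:
        raise ValueError("motif must be a hexamer")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    fwd = rotations(motif)
    rev = rotations(revcomp(motif)) - fwd  # palindromic families collapse
    seq = contig.seq
    n = len(seq)

    strand_at = {}  # match start -> strand
    for i in range(n - 5):
        w = seq[i:i + 6]
        if w in fwd:
            strand_at[i] = "same"
        elif w in rev:
            strand_at[i] = "reverse-complement"
    positions = sorted(strand_at)

    arrays: list[TMRArray] = []

    def flush(cluster):
        if len(cluster) < min_copies:
            return
        s = cluster[0]
        e = cluster[-1] + 6
        n_same = sum(1 for p in cluster if strand_at[p] == "same")
        orient = "same" if n_same >= len(cluster) - n_same else \
            "reverse-complement"
        arrays.append(TMRArray(
            contig_id=contig.id, start=s, end=e,
            motif=canonical_motif(motif), orientation=orient,
            copies=len(cluster),
            purity=len(cluster) / ((e - s) // 6),
            query_motif=motif,
        ))

    # non-overlapping tiling, preferring the copy in phase with the
    # cluster's start so a degraded internal copy does not shift the frame
    i = 0
    cluster: list[int] = []
    while i < len(positions):
        if not cluster:
            cluster.append(positions[i])
            i += 1
            continue
        prev_end = cluster[-1] + 6
        phase = cluster[0] % 6
        window = [p for p in positions[i:]
                  if prev_end <= p <= prev_end + max_gap]
        in_phase = [p for p in window if p % 6 == phase]
        nxt = in_phase[0] if in_phase else (window[0] if window else None)
        if nxt is None:
            flush(cluster)
            cluster = []
            while i < len(positions) and positions[i] < prev_end:
                i += 1
            continue
        cluster.append(nxt)
        while i < len(positions) and positions[i] <= nxt:
            i += 1
    flush(cluster)
    return arrays


def motif_orientation(array: TMRArray, reference_motif: str) -> str:
    """Orientation of a detected array relative to a reference motif.

    Rotations share an orientation; only a strand flip changes it.  The
    array's recorded orientation is re-expressed against the reference,
    which must lie in the rotation/strand closure of the array's family.
    """
    if reference_motif in rotations(array.query_motif):
        return array.orientation
    if reference_motif in rotations(revcomp(array.query_motif)):
        return ("reverse-complement" if array.orientation == "same"
                else "same")
    raise ValueError(
        f"{reference_motif} is not in the rotation/strand closure of "
        f"the array family {array.motif}"
    )


@dataclass
class JunctionCall:
    """A host/virus junction mediated by a telomeric-repeat array."""

    contig_id: str
    coordinate: int
    host_side: tuple        # (start, end) of host evidence
    virus_side: tuple       # (start, end) spanned by viral hits
    viral_hit_ids: list
    array: TMRArray

    def __post_init__(self) -> None:
        host_mid = 0.5 * (self.host_side[0] + self.host_side[1])
        virus_mid = 0.5 * (self.virus_side[0] + self.virus_side[1])
        if (host_mid - self.coordinate) * (virus_mid - self.coordinate) > 0:
            raise ValueError("host and virus evidence on the same side")


def call_junction(
    contig: SequenceRecord,
    arrays: list[TMRArray],
    viral_hits,
    host_intervals: list[tuple[int, int]],
) -> list[JunctionCall]:
    """Call junctions at arrays separating viral hits from host evidence.

    A candidate is any array with viral hits on exactly one side and host
    evidence (and no viral hit) on the other; among candidates of the same
    polarity the one nearest the host side is the junction (arrays internal
    to the viral direct repeats also separate the two kinds of evidence,
    but the host/virus boundary is the array the host flank runs into).
    The junction coordinate is the array edge nearest the viral side.
    """
    if not arrays:
        raise ValueError("contig has no TMR array")
    hit_ivs = [(h.subject_start, h.subject_end, getattr(h, "query_id", "?"))
               for h in viral_hits]
    calls = []
    for arr in arrays:
        def side_content(lo, hi):
            viral = [(s, e, q) for s, e, q in hit_ivs
                     if s < hi and e > lo]
            host = [(s, e) for s, e in host_intervals if s < hi and e > lo]
            return viral, host

        left_viral, left_host = side_content(0, arr.start)
        right_viral, right_host = side_content(arr.end, len(contig.seq))
        if left_viral and not right_viral and right_host:
            virus_side = (min(s for s, _, _ in left_viral),
                          max(e for _, e, _ in left_viral))
            host_side = (min(s for s, _ in right_host),
                         max(e for _, e in right_host))
            calls.append(JunctionCall(
                contig.id, arr.start, host_side, virus_side,
                [q for _, _, q in left_viral], arr))
        elif right_viral and not left_viral and left_host:
            virus_side = (min(s for s, _, _ in right_viral),
                          max(e for _, e, _ in right_viral))
            host_side = (min(s for s, _ in left_host),
                         max(e for _, e in left_host))
            calls.append(JunctionCall(
                contig.id, arr.end, host_side, virus_side,
                [q for _, _, q in right_viral], arr))
    # keep, per polarity, the candidate nearest the host side
    viral_right = [c for c in calls if c.coordinate == c.array.end]
    viral_left = [c for c in calls if c.coordinate == c.array.start]
    kept = []
    if viral_right:
        kept.append(min(viral_right, key=lambda c: c.array.start))
    if viral_left:
        kept.append(max(viral_left, key=lambda c: c.array.end))
    return kept


@dataclass
class OverlapAlignment:
    """Semi-global suffix/prefix overlap between two contig termini."""

    contig_a: str
    contig_b: str
    length: int         # alignment columns
    mismatches: int
    gaps: int           # gap columns
    orientation: str    # 'forward' | 'reverse-complement' (of B)
    a_is_suffix: bool   # True: suffix of A overlaps prefix of B

    def __post_init__(self) -> None:
        if self.length < self.mismatches:
            raise ValueError("more mismatches than columns")


def _overlap_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _suffix_prefix(a_seq: str, b_seq: str):
    """Best overlap of a suffix of a_seq with a prefix of b_seq."""
    al = _overlap_aligner()
    # a is target: free gaps in the QUERY (b) at the LEFT leave a's prefix
    # unaligned; free gaps in the TARGET (a) at the RIGHT leave b's suffix
    # unaligned — forcing the alignment onto a's suffix and b's prefix.
    al.open_left_deletion_score = 0.0      # a's prefix may go unaligned
    al.extend_left_deletion_score = 0.0
    al.open_right_insertion_score = 0.0    # b's suffix may go unaligned
    al.extend_right_insertion_score = 0.0
    alns = al.align(a_seq, b_seq)
    return alns[0], alns.score


def _overlap_stats(aln):
    """(columns, mismatches, gap_cols) over the overlap region only."""
    ta, qa = aln.aligned[0], aln.aligned[1]
    if len(ta) == 0:
        return 0, 0, 0
    t_str = str(aln.sequences[0])
    q_str = str(aln.sequences[1])
    cols = 0
    mism = 0
    gaps = 0
    for k in range(len(ta)):
        a0, a1 = ta[k]
        b0, b1 = qa[k]
        cols += a1 - a0
        for x, y in zip(t_str[a0:a1], q_str[b0:b1]):
            if x != y:
                mism += 1
        if k:
            g = max(ta[k][0] - ta[k - 1][1], qa[k][0] - qa[k - 1][1])
            gaps += g
            cols += g
    return cols, mism, gaps


def terminal_overlap(
    contig_a: SequenceRecord,
    contig_b: SequenceRecord,
    min_len: int = 20,
    min_identity: float = 0.9,
    max_window: int = 2000,
) -> OverlapAlignment | None:
    """Best terminal overlap between two contigs, both orientations tried.

    Considers suffix(A)/prefix(B) and suffix(B)/prefix(A), with B also
    reverse-complemented; windows are capped at ``max_window`` bp from each
    terminus.  Returns None when no overlap reaches ``min_len`` columns at
    ``min_identity``.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    candidates = []
    b_variants = [(contig_b.seq, "forward"),
                  (revcomp(contig_b.seq), "reverse-complement")]
    for b_seq, orient in b_variants:
        for a_first in (True, False):
            if a_first:
                left = contig_a.seq[-max_window:]
                right = b_seq[:max_window]
            else:
                left = b_seq[-max_window:]
                right = contig_a.seq[:max_window]
            aln, _ = _suffix_prefix(left, right)
            cols, mism, gaps = _overlap_stats(aln)
            if cols >= min_len and (cols - mism - gaps) / cols >= min_identity:
                candidates.append(OverlapAlignment(
                    contig_a.id, contig_b.id, cols, mism, gaps,
                    orientation=orient, a_is_suffix=a_first))
    if not candidates:
        return None
    return max(candidates, key=lambda o: o.length - o.mismatches - o.gaps)
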