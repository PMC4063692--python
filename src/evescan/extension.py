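"""Targeted scaffolding: iterative mate-pair extension of contig edges.

Each contig edge is walked outwards a few tens of bases at a time: reads
overlapping the current edge by at least ``min_overlap`` (found through a
k-mer index of both mates on both strands, plus insert-size-guided rescue
of the mates of anchored reads) vote on the overhanging columns, and the
column-wise majority base is appended while its support stays at or above
``min_support``.  Two disagreeing candidates that both reach the support
floor stop the walk as ambiguous — the deterministic replacement for the
by-eye curation such extensions otherwise need.  Extended edges are then
linked to other contigs by suffix/prefix overlap, and chains of links are
merged into composite contigs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .records import SequenceRecord, revcomp
from .synthetic import ReadPair


@dataclass
class ReadIndex:
    """k-mer postings over both mates and strands of a read set."""

    k: int
    reads: dict                      # read id -> oriented-as-stored sequence
    postings: dict                   # kmer -> list of (read id, offset, strand)
    mate_of: dict                    # read id -> mate read id
    insert_mean: float

    def candidates(self, seq: str) -> set:
        """(read id, strand) pairs sharing a k-mer with ``seq``."""
        out = set()
        for i in range(len(seq) - self.k + 1):
            for rid, _, strand in self.postings.get(seq[i:i + self.k], ()):
                out.add((rid, strand))
        return out

    def oriented(self, rid: str, strand: str) -> str:
        r = self.reads[rid]
        return r if strand == "+" else revcomp(r)


def index_reads(pairs: list[ReadPair], k: int = 21) -> ReadIndex:
    """Index both mates of every pair on both strands."""
    if k < 8:
        raise ValueError("k < 8 invites spurious matches")
    reads = {}
    postings = defaultdict(list)
    mate_of = {}
    inserts = []
    for p in pairs:
        for rec in (p.read1, p.read2):
            if k > len(rec.seq):
                raise ValueError("k exceeds read length")
            if rec.id in reads:
                raise ValueError(f"duplicate read id {rec.id!r}")
            reads[rec.id] = rec.seq
        mate_of[p.read1.id] = p.read2.id
        mate_of[p.read2.id] = p.read1.id
        inserts.append(p.insert_size)
        for rec in (p.read1, p.read2):
            for strand, s in (("+", rec.seq), ("-", revcomp(rec.seq))):
                for i in range(len(s) - k + 1):
                    postings[s[i:i + k]].append((rec.id, i, strand))
    return ReadIndex(k=k, reads=reads, postings=dict(postings),
                     mate_of=mate_of,
                     insert_mean=(sum(inserts) / len(inserts)) if inserts
                     else 0.0)


@dataclass
class ContigExtension:
    """Result of walking one contig edge outwards."""

    contig_id: str
    side: str                       # 'left' | 'right'
    appended: str                   # forward-strand bases, outward order
    support: list                   # per appended base
    iterations: int
    termination: str                # ambiguous | exhausted | max-iterations

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if len(self.appended) != len(self.support):
            raise ValueError("support must cover every appended base")

    @property
    def extended_sequence_suffix(self) -> str:
        return self.appended


def _align_offset(read: str, seq: str, offset: int, min_overlap: int,
                  max_mismatch_frac: float) -> bool:
    """Does ``read`` placed at ``offset`` on ``seq`` agree over the overlap?"""
    lo = max(0, offset)
    hi = min(len(seq), offset + len(read))
    overlap = hi - lo
    if overlap < min_overlap:
        return False
    mism = sum(1 for i in range(lo, hi) if seq[i] != read[i - offset])
    return mism <= max_mismatch_frac * overlap


def _best_offset(read: str, seq: str, kmer_index_k: int) -> int | None:
    """Offset of read on seq implied by its left-most shared k-mer."""
    k = kmer_index_k
    window = seq[-(len(read) + 200):]
    base = len(seq) - len(window)
    pos_in_window = {}
    for i in range(len(window) - k + 1):
        pos_in_window.setdefault(window[i:i + k], i)
    for j in range(len(read) - k + 1):
        i = pos_in_window.get(read[j:j + k])
        if i is not None:
            return base + i - j
    return None


def extend_edge(
    contig: SequenceRecord,
    side: str,
    index: ReadIndex,
    min_overlap: int = 30,
    min_support: int = 3,
    max_mismatch_frac: float = 0.02,
    max_iterations: int = 200,
    max_append: int = 400,
) -> ContigExtension:
    """Iteratively extend one edge of a contig by read-majority consensus.

    Deterministic: ties at or above the support floor terminate the walk
    with reason 'ambiguous'.  The appended sequence is reported in
    forward-strand outward order (prepend ``appended[::-1]``-style handling
    is done by the caller for the left side via reverse complement).
    """
    if min_overlap < index.k:
        raise ValueError("min_overlap must be >= index k")
    work = contig.seq if side == "right" else revcomp(contig.seq)
    appended: list[str] = []
    support: list[int] = []
    termination = "max-iterations"
    it = 0
    read_len_max = max((len(r) for r in index.reads.values()), default=0)
    while it < max_iterations:
        it += 1
        edge = work[-(read_len_max + 50):]
        cand = index.candidates(edge)
        # mate rescue: mates of anchored candidates, at the insert-implied
        # offset (they may share no k-mer with the edge yet)
        placements = {}
        for rid, strand in cand:
            read = index.oriented(rid, strand)
            off = _best_offset(read, work, index.k)
            if off is None:
                continue
            if _align_offset(read, work, off, min_overlap,
                             max_mismatch_frac):
                placements[(rid, strand)] = off
        for (rid, strand), off in list(placements.items()):
            mate = index.mate_of[rid]
            if any(m == mate for m, _ in placements):
                continue
            # anchored read on '+' implies mate on '-' further out
            mate_read = index.oriented(mate, "-" if strand == "+" else "+")
            m_off = off + int(index.insert_mean) - len(mate_read)
            for shift in range(-30, 31):
                cand_off = m_off + shift
                if cand_off + len(mate_read) <= len(work):
                    continue
                if _align_offset(mate_read, work, cand_off,
                                 max(12, index.k), max_mismatch_frac):
                    placements[(mate, "-" if strand == "+" else "+")] = \
                        cand_off
                    break

        votes: dict[int, Counter] = defaultdict(Counter)
        for (rid, strand), off in placements.items():
            read = index.oriented(rid, strand)
            for p in range(max(len(work), off), off + len(read)):
                votes[p][read[p - off]] += 1

        new_bases = []
        new_support = []
        ambiguous = False
        capped = False
        pos = len(work)
        while pos in votes:
            if len(appended) + len(new_bases) >= max_append:
                capped = True
                break
            counts = votes[pos].most_common()
            best_base, best_n = counts[0]
            if best_n < min_support:
                break
            if len(counts) > 1 and counts[1][1] >= min_support:
                ambiguous = True
                break
            new_bases.append(best_base)
            new_support.append(best_n)
            pos += 1
        if new_bases:
            work = work + "".join(new_bases)
            appended.extend(new_bases)
            support.extend(new_support)
        if ambiguous:
            termination = "ambiguous"
            break
        if capped:
            termination = "max-iterations"
            break
        if not new_bases:
            termination = "exhausted"
            break
    out = "".join(appended)
    if side == "left":
        out = revcomp(out)
    return ContigExtension(contig.id, side, out, support[::(-1 if side ==
                           "left" else 1)], it, termination)


@dataclass
class CompositeContig:
    """Ordered members joined through overlap evidence."""

    members: list            # (contig id, orientation '+'|'-')
    sequence: str
    joins: list              # (left id, right id, overlap bp, mean support)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a composite needs at least two members")


def _suffix_prefix_overlap(a: str, b: str, min_overlap: int,
                           max_mismatch_frac: float,
                           max_search: int = 600) -> int:
    """Largest o with a[-o:] ~= b[:o]; 0 when none reaches min_overlap."""
    top = min(len(a), len(b), max_search)
    for o in range(top, min_overlap - 1, -1):
        mism = sum(1 for x, y in zip(a[-o:], b[:o]) if x != y)
        if mism <= max_mismatch_frac * o:
            return o
    return 0


def link_contigs(
    extensions: list[ContigExtension],
    contigs: list[SequenceRecord],
    min_overlap: int = 30,
    max_mismatch_frac: float = 0.02,
) -> tuple[list[CompositeContig], dict]:
    """Join extended edges to other contigs by terminal overlap.

    Conflicting joins (one edge matching two partners) are left unjoined
    and reported; circular chains are reported, not constructed.
    """
    by_id = {c.id: c.seq for c in contigs}
    ext = {(e.contig_id, e.side): e for e in extensions}

    def extended_right(cid):
        e = ext.get((cid, "right"))
        return by_id[cid] + (e.appended if e else "")

    candidates = defaultdict(list)  # cid -> list of (partner, orient, o)
    for cid in by_id:
        a_seq = extended_right(cid)
        for other in by_id:
            if other == cid:
                continue
            for orient in ("+", "-"):
                b_seq = by_id[other] if orient == "+" else \
                    revcomp(by_id[other])
                o = _suffix_prefix_overlap(a_seq, b_seq, min_overlap,
                                           max_mismatch_frac)
                if o:
                    candidates[cid].append((other, orient, o))

    report = {"conflicts": [], "circular": []}
    joins = {}
    joined_as_right = set()
    for cid, cands in candidates.items():
        partners = {p for p, _, _ in cands}
        if len(partners) > 1:
            report["conflicts"].append((cid, sorted(partners)))
            continue
        partner, orient, o = max(cands, key=lambda t: t[2])
        if partner in joined_as_right:
            report["conflicts"].append((cid, [partner]))
            continue
        joins[cid] = (partner, orient, o)
        joined_as_right.add(partner)

    composites = []
    starts = [c for c in joins if c not in joined_as_right]
    consumed = set()
    for start in starts:
        chain = [(start, "+")]
        seq = extended_right(start)
        cur = start
        seen = {start}
        join_ev = []
        while cur in joins:
            nxt, orient, o = joins[cur]
            if nxt in seen:
                report["circular"].append(chain[:])
                break
            b_full = by_id[nxt] if orient == "+" else revcomp(by_id[nxt])
            seq = seq[: len(seq) - o] + b_full
            e = ext.get((nxt, "right"))
            if e and orient == "+":
                seq = seq + e.appended
            chain.append((nxt, orient))
            join_ev.append((cur, nxt, o, 0.0))
            seen.add(nxt)
            cur = nxt
        if len(chain) >= 2:
            composites.append(CompositeContig(chain, seq, join_ev))
            consumed |= seen
    return composites, report


def scaffold_targeted(
    contigs: list[SequenceRecord],
    pairs: list[ReadPair],
    gene_order_hint: list | None = None,
    contig_proteins: dict | None = None,
    k: int = 21,
    min_overlap: int = 30,
    min_support: int = 3,
    max_mismatch_frac: float = 0.02,
) -> tuple[list[CompositeContig], dict]:
    """Extend every contig edge, then link extended edges into composites.

    When an expected gene order is given (with per-contig protein content),
    joins contradicting that order are demoted to 'flagged' in the report
    rather than applied.
    """
    if not pairs:
        return [], {"note": "empty read set; contigs returned unchanged",
                    "flagged": []}
    index = index_reads(pairs, k=k)
    extensions = []
    for c in contigs:
        for side in ("left", "right"):
            extensions.append(extend_edge(
                c, side, index, min_overlap=min_overlap,
                min_support=min_support,
                max_mismatch_frac=max_mismatch_frac))
    composites, report = link_contigs(extensions, contigs,
                                      min_overlap=min_overlap,
                                      max_mismatch_frac=max_mismatch_frac)
    report.setdefault("flagged", [])
    if gene_order_hint and contig_proteins:
        rank = {p: i for i, p in enumerate(gene_order_hint)}

        def first_rank(cid):
            rs = [rank[p] for p in contig_proteins.get(cid, ())
                  if p in rank]
            return min(rs) if rs else None

        kept = []
        for comp in composites:
            ranks = [first_rank(cid) for cid, _ in comp.members]
            known = [r for r in ranks if r is not None]
            if known != sorted(known):
                report["flagged"].append(
                    [cid for cid, _ in comp.members])
            else:
                kept.append(comp)
        composites = kept
    return composites, report
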