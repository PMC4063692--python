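"""Coding-degradation profiling and endogenous/exogenous provenance calls.

An endogenous viral element drifts neutrally, so its genes accumulate
premature stop codons and frameshifts; an exogenous contaminant genome
keeps its ORFs intact.  Degradation is measured per reference protein by
chaining frame-consistent translated local alignments across the matched
contig region: a transition between chained segments in different reading
frames counts as one frameshift, and '*' characters inside aligned
segments (never the terminal stop) count as premature stops.
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import (ScoringScheme, TranslatedHit, six_frame_translate,
                       translated_search)
from .junctions import JunctionCall
from .records import SequenceRecord


@dataclass
class ORFDegradationReport:
    """Integrity of one reference protein's footprint on a contig."""

    protein_id: str
    contig_id: str
    region: tuple            # (start, end) nt on the contig, forward coords
    premature_stops: int
    frameshifts: int
    covered_fraction: float
    intact: bool

    def __post_init__(self) -> None:
        expected = (self.premature_stops == 0 and self.frameshifts == 0
                    and self.covered_fraction >= 0.0)
        if self.intact and not expected:
            raise ValueError("intact flag inconsistent with counts")


def profile_orf_integrity(
    contig: SequenceRecord,
    reference_protein: SequenceRecord,
    scoring: ScoringScheme | None = None,
    min_raw_score: float = 30.0,
    covered_threshold: float = 0.8,
) -> ORFDegradationReport:
    """Count premature stops and frameshifts against a reference protein.

    Translated hits of the reference against the contig are chained in
    query order, keeping frame-consistent non-overlapping segments; each
    frame change between consecutive chained segments is one frameshift.
    """
    hits = translated_search(reference_protein, [contig], scoring,
                             min_raw_score=min_raw_score,
                             max_hits_per_frame=8)
    if not hits:
        return ORFDegradationReport(
            reference_protein.id, contig.id, (0, 0), 0, 0, 0.0, False)

    # chain greedily by query coordinate; short query overlaps (alignment
    # slop around a frameshift breakpoint) are tolerated
    overlap_tol = 10
    chain: list[TranslatedHit] = []
    for h in sorted(hits, key=lambda h: (h.query_start, -h.score)):
        if not chain or (h.query_start >= chain[-1].query_end - overlap_tol
                         and h.query_end > chain[-1].query_end):
            chain.append(h)

    frames = six_frame_translate(contig)
    stops = 0
    for h in chain:
        prot = frames[h.frame]
        # aa coordinates of the hit within its frame
        off = abs(h.frame) - 1
        if h.frame > 0:
            aa0 = (h.subject_start - off) // 3
        else:
            aa0 = (len(contig.seq) - h.subject_end - off) // 3
        aa1 = aa0 + (h.subject_end - h.subject_start) // 3
        seg = prot[aa0:aa1]
        n_stop = seg.count("*")
        # a stop aligned at the reference's terminal position is natural
        if seg.endswith("*") and h.query_end >= len(reference_protein.seq):
            n_stop -= 1
        stops += n_stop

    frameshifts = sum(
        1 for a, b in zip(chain, chain[1:]) if a.frame != b.frame
    )
    covered = sum(h.query_end - h.query_start for h in chain) / \
        len(reference_protein.seq)
    covered = min(covered, 1.0)
    region = (min(h.subject_start for h in chain),
              max(h.subject_end for h in chain))
    intact = (stops == 0 and frameshifts == 0
              and covered >= covered_threshold)
    return ORFDegradationReport(
        reference_protein.id, contig.id, region, stops, frameshifts,
        covered, intact)


@dataclass
class ProvenanceCall:
    """Endogenous-like vs exogenous-like verdict for a contig set."""

    contig_set_id: str
    verdict: str             # endogenous-like | exogenous-like | ambiguous
    nonsense_mutations: bool
    junction_present: bool
    te_acquired: bool
    disrupted_fraction: float

    def __post_init__(self) -> None:
        if self.verdict not in ("endogenous-like", "exogenous-like",
                                "ambiguous"):
            raise ValueError(f"bad verdict {self.verdict!r}")


def classify_provenance(
    reports: list[ORFDegradationReport],
    junctions: list[JunctionCall],
    te_flag: bool = False,
    disrupted_threshold: float = 0.5,
    contig_set_id: str = "candidate",
) -> ProvenanceCall:
    """Deterministic provenance rules over degradation and junction evidence.

    endogenous-like: disrupted-ORF fraction >= threshold OR a host-flank
    junction is present.  exogenous-like: zero disruptions, no junction and
    no transposable-element acquisition.  Anything else: ambiguous.
    """
    if not reports:
        raise ValueError("need at least one degradation report")
    disrupted = [r for r in reports
                 if r.premature_stops > 0 or r.frameshifts > 0]
    frac = len(disrupted) / len(reports)
    junction_present = bool(junctions)
    nonsense = bool(disrupted)
    if frac >= disrupted_threshold or junction_present:
        verdict = "endogenous-like"
    elif not nonsense and not junction_present and not te_flag:
        verdict = "exogenous-like"
    else:
        verdict = "ambiguous"
    return ProvenanceCall(contig_set_id, verdict, nonsense,
                          junction_present, te_flag, frac)
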