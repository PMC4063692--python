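"""Synthetic draft assemblies with a dated endogenous viral insertion.

This module generates the study conditions for every downstream stage: a host
genome carrying a telomeric-repeat (TMR) junction, a roseolovirus-like viral
genome (two direct repeats, each with a perfect and an imperfect TMR array,
flanking a unique region of protein-coding ORFs), neutral sequence evolution
of the integrated copy under a general time-reversible (GTR) model, paired
reads with a truncated-normal insert-size distribution, and repeat-driven
assembly fragmentation.  Every generator returns full ground truth so that
parameter recovery can be tested without any external data.

Substitutions are simulated as a per-site continuous-time Markov jump process
with the generator normalised to one expected substitution per site per unit
of ``rate * time``, so the expected raw event count over a sequence of length
L after divergence d is simply L*d.  Indels are not simulated by default: the
dating stage assumes a colinear ancestor/descendant pair.  An optional indel
channel exists for stress testing only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import SequenceRecord, revcomp

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

# codon table helpers come from Biopython at the point of use (degradation
# truth); here we only need stop codons for ORF construction
STOP_CODONS = ("TAA", "TAG", "TGA")

#: exchangeability order used throughout: (AC, AG, AT, CG, CT, GT)
EXCHANGEABILITY_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class GTRModel:
    """General time-reversible substitution model.

    Parameters
    ----------
    exchangeabilities : array-like, shape (6,)
        Symmetric rate multipliers in the order AC, AG, AT, CG, CT, GT.
    freqs : array-like, shape (4,)
        Stationary base frequencies (A, C, G, T); must sum to 1.
    """

    exchangeabilities: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, float)
        self.freqs = np.asarray(self.freqs, float)
        if self.exchangeabilities.shape != (6,):
            raise ValueError("need 6 exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if np.any(self.exchangeabilities < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if self.freqs.shape != (4,) or np.any(self.freqs < 0) or \
                not np.isclose(self.freqs.sum(), 1.0, atol=1e-8):
            raise ValueError("freqs must be 4 non-negative values summing to 1")

    @classmethod
    def equal_rates(cls) -> "GTRModel":
        """Jukes–Cantor special case: equal rates, uniform frequencies."""
        return cls(np.ones(6), np.full(4, 0.25))

    def rate_matrix(self) -> np.ndarray:
        """Normalised generator Q with expected rate 1 substitution/site.

        Degenerate all-zero models return the zero matrix (allowed: a frozen
        sequence).
        """
        s = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for k, (i, j) in enumerate(pairs):
            s[i, j] = s[j, i] = self.exchangeabilities[k]
        q = s * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        if mu > 0:
            q = q / mu
        return q


def evolve_neutrally(
    seq: SequenceRecord,
    rate: float,
    time: float,
    model: GTRModel | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SequenceRecord, int]:
    """Evolve a DNA sequence by a per-site CTMC and count raw events.

    ``rate`` is in substitutions/site/year and ``time`` in years; their
    product is the expected number of substitution events per site.  Sites
    containing ``N`` are left untouched.  Returns the evolved record and the
    total number of substitution events (multiple hits at one site each
    count).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if model is None:
        model = GTRModel.equal_rates()
    d = rate * time
    if not np.isfinite(d) or d < 0:
        raise ValueError("rate*time must be finite and non-negative")
    if d == 0:
        return SequenceRecord(seq.id, seq.seq, "dna", seq.description), 0

    q = model.rate_matrix()
    leave = -np.diag(q)  # per-state total leave rate (normalised units)
    with np.errstate(divide="ignore", invalid="ignore"):
        jump = np.where(leave[:, None] > 0, q / leave[:, None], 0.0)
    np.fill_diagonal(jump, 0.0)
    jump_cum = np.cumsum(jump, axis=1)

    arr = np.frombuffer(seq.seq.encode(), dtype="S1")
    mutable = arr != b"N"
    state = np.zeros(len(arr), dtype=np.int8)
    for b, i in _BASE_IDX.items():
        state[arr == b.encode()] = i

    idx = np.flatnonzero(mutable)
    t = np.zeros(idx.size)
    events = 0
    while idx.size:
        lam = leave[state[idx]]  # in units of subs/site; total clock = d
        alive = lam > 0
        idx = idx[alive]
        if not idx.size:
            break
        t = t[alive] + rng.exponential(1.0 / (leave[state[idx]]))
        alive = t < d
        idx, t = idx[alive], t[alive]
        if not idx.size:
            break
        u = rng.random(idx.size)
        rows = jump_cum[state[idx]]
        new_state = (u[:, None] > rows).sum(axis=1).astype(np.int8)
        new_state = np.minimum(new_state, 3)
        state[idx] = new_state
        events += idx.size

    out = np.array(list(BASES), dtype="U1")[state]
    out_chars = np.frombuffer(seq.seq.encode(), dtype="S1").astype("U1").copy()
    out_chars[mutable] = out[mutable]
    return (
        SequenceRecord(seq.id, "".join(out_chars), "dna", seq.description),
        events,
    )


def random_dna(rng: np.random.Generator, length: int,
               freqs=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=list(freqs)))


def random_dna_avoiding(rng: np.random.Generator, length: int,
                        forbidden: set) -> str:
    """Random DNA free of any hexamer in ``forbidden``.

    Used for the sequence flanking telomeric-repeat arrays so the array
    boundary is a well-defined ground truth (a chance motif copy right
    next to an array would make the true edge ambiguous).
    """
    chars = list(random_dna(rng, length))
    k = 6
    changed = True
    while changed:
        changed = False
        for i in range(max(0, length - k + 1)):
            if "".join(chars[i:i + k]) in forbidden:
                j = i + int(rng.integers(0, k))
                chars[j] = rng.choice(
                    [b for b in BASES if b != chars[j]])
                changed = True
    return "".join(chars)


def _random_orf(rng: np.random.Generator, aa_len: int) -> str:
    """ATG + random internal non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < aa_len:
        c = random_dna(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


@dataclass
class ViralGenomeModel:
    """Schematic roseolovirus-like genome: DR + unique region + DR.

    Each direct repeat (DR) carries two telomeric-repeat arrays: a perfect
    one at the terminus that faces the host on integration and an imperfect
    one internal to the DR.  The unique region carries synthetic
    protein-coding ORFs on both strands.
    """

    sequence: str
    motif: str
    orfs: list  # (protein_id, start, end, strand) 0-based half-open
    dr_intervals: list  # [(start, end), (start, end)]
    tmr_intervals: list  # [(start, end, is_perfect), ...]
    proteins: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.motif) != 6:
            raise ValueError("TMR motif must be a hexamer")
        for s, e, _ in self.tmr_intervals:
            if (e - s) < 12:
                raise ValueError("TMR arrays must hold at least 2 copies")


def build_viral_genome(
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    motif: str = "TAACCC",
    perfect_copies: int = 49,
    imperfect_copies: int = 25,
    dr_pad: int = 150,
    n_orfs: int = 5,
    orf_aa_len: tuple[int, int] = (120, 260),
    intergenic: int = 80,
) -> ViralGenomeModel:
    """Assemble a synthetic viral genome model.

    The perfect TMR defaults to 49 motif copies (294 bp), matching the size
    class of roseolovirus DR telomeric arrays; the imperfect array has ~20%
    of copies carrying a single substitution.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    from Bio.Seq import Seq

    forbidden = _rotation_closure(motif)
    perfect = motif * perfect_copies

    copies = []
    for _ in range(imperfect_copies):
        c = list(motif)
        if rng.random() < 0.2:
            pos = rng.integers(0, 6)
            c[pos] = rng.choice([b for b in BASES if b != c[pos]])
        copies.append("".join(c))
    imperfect = "".join(copies)

    # terminus-facing perfect array first: on integration through the left
    # DR the perfect array recombines with the host telomere; pads are
    # motif-free so array boundaries are exact ground truth
    dr_body = perfect + random_dna_avoiding(rng, dr_pad, forbidden) + \
        imperfect + random_dna_avoiding(rng, dr_pad, forbidden)

    unique_parts = [random_dna_avoiding(rng, intergenic, forbidden)]
    orfs = []
    proteins = {}
    pos = len(dr_body) + intergenic
    for k in range(n_orfs):
        aa = int(rng.integers(orf_aa_len[0], orf_aa_len[1] + 1))
        cds = _random_orf(rng, aa)
        strand = 1 if k % 2 == 0 else -1
        pid = f"VP{k + 1:02d}"
        if strand == 1:
            unique_parts.append(cds)
            orfs.append((pid, pos, pos + len(cds), 1))
            proteins[pid] = str(Seq(cds).translate())[:-1]
        else:
            unique_parts.append(revcomp(cds))
            orfs.append((pid, pos, pos + len(cds), -1))
            proteins[pid] = str(Seq(cds).translate())[:-1]
        pos += len(cds)
        spacer = random_dna(rng, intergenic)
        unique_parts.append(spacer)
        pos += intergenic
    unique = "".join(unique_parts)

    seq = dr_body + unique + dr_body
    dr_len = len(dr_body)
    tmr = []
    for off in (0, dr_len + len(unique)):
        tmr.append((off, off + len(perfect), True))
        ims = off + len(perfect) + dr_pad
        tmr.append((ims, ims + len(imperfect), False))
    return ViralGenomeModel(
        sequence=seq, motif=motif, orfs=orfs,
        dr_intervals=[(0, dr_len), (dr_len + len(unique), len(seq))],
        tmr_intervals=tmr, proteins=proteins,
    )


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests."""

    integration_site: int          # host coordinate where the virus begins
    junction_call_truth: int       # expected junction call (embedded coords):
    # the viral-side edge of the junction-mediating TMR array
    viral_interval: tuple          # (start, end) of virus in embedded coords
    age_years: float
    rate: float                    # substitutions/site/year
    orf_disruptions: dict          # protein id -> {"stops": int, "frameshifts": int}
    gap_intervals: list = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age must be non-negative")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


ROTATION_CLOSURE_CACHE: dict = {}


def _rotation_closure(motif: str) -> set:
    key = motif
    if key not in ROTATION_CLOSURE_CACHE:
        rots = {motif[i:] + motif[:i] for i in range(len(motif))}
        rc = revcomp(motif)
        rots |= {rc[i:] + rc[:i] for i in range(len(rc))}
        ROTATION_CLOSURE_CACHE[key] = rots
    return ROTATION_CLOSURE_CACHE[key]


def build_host(
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    length: int = 8000,
    motif: str = "TAACCC",
    telomere_copies: int = 30,
    telomere_pos: int | None = None,
) -> tuple[SequenceRecord, tuple[int, int]]:
    """Random host sequence with one interstitial telomeric array.

    Returns the host record and the (start, end) of the telomeric array.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tel = motif * telomere_copies
    if telomere_pos is None:
        telomere_pos = (2 * length) // 3
    flank_a = random_dna(rng, telomere_pos)
    flank_b = random_dna(rng, max(0, length - telomere_pos - len(tel)))
    seq = flank_a + tel + flank_b
    return (
        SequenceRecord("host", seq, "dna"),
        (telomere_pos, telomere_pos + len(tel)),
    )


def count_orf_stops(seq: str, orf: tuple) -> int:
    """Internal stop codons in an ORF of the (possibly mutated) genome."""
    from Bio.Seq import Seq

    _, s, e, strand = orf
    cds = seq[s:e] if strand == 1 else revcomp(seq[s:e])
    aa = str(Seq(cds[: 3 * (len(cds) // 3)]).translate())
    return aa[:-1].count("*")  # terminal stop never premature


def embed_viral_insertion(
    host: SequenceRecord,
    virus: ViralGenomeModel,
    site: int,
    age: float,
    rate: float,
    model: GTRModel | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SequenceRecord, GroundTruth]:
    """Insert a neutrally aged copy of the virus at a host telomeric site.

    The host sequence upstream of ``site`` ends inside a telomeric array;
    the virus joins through the perfect TMR at its left DR terminus, so the
    host array and the viral perfect array fuse into the junction-mediating
    array.  Disruption truth is recomputed from the evolved sequence, not
    pre-assigned.
    """
    if not (0 <= site <= len(host.seq)):
        raise ValueError("integration site outside host bounds")
    if rng is None:
        rng = np.random.default_rng(seed)

    evolved, _ = evolve_neutrally(
        SequenceRecord("virus", virus.sequence, "dna"),
        rate, age, model=model, rng=rng,
    )
    disruptions = {}
    for orf in virus.orfs:
        disruptions[orf[0]] = {
            "stops": count_orf_stops(evolved.seq, orf),
            "frameshifts": 0,  # no indel channel in the default generator
        }
    embedded = host.seq[:site] + evolved.seq + host.seq[site:]
    perfect_len = next(
        e - s for s, e, p in virus.tmr_intervals if p and s == 0
    )
    truth = GroundTruth(
        integration_site=site,
        junction_call_truth=site + perfect_len,
        viral_interval=(site, site + len(evolved.seq)),
        age_years=age,
        rate=rate,
        orf_disruptions=disruptions,
        seed=seed,
    )
    return (
        SequenceRecord(host.id + "_theve", embedded, "dna",
                       description="host with endogenous viral insertion"),
        truth,
    )


@dataclass
class ReadPair:
    """A simulated mate pair with its origin truth."""

    read1: SequenceRecord
    read2: SequenceRecord
    insert_size: int
    origin: tuple  # (start, end) on the source genome, forward coords
    strand: int = 1

    def __post_init__(self) -> None:
        if self.insert_size < max(len(self.read1.seq), len(self.read2.seq)):
            raise ValueError("insert smaller than a read")


def simulate_reads(
    genome: SequenceRecord,
    read_len: int = 100,
    insert_mean: int = 300,
    insert_sd: float = 30.0,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[ReadPair]:
    """Paired reads at the given fold coverage.

    Insert sizes are normal(insert_mean, insert_sd) truncated below at
    2*read_len; read 1 is the forward strand at the fragment start, read 2
    the reverse complement at the fragment end.  Expected pair count is
    coverage * L / (2 * read_len).
    """
    if insert_sd < 0:
        raise ValueError("insert_sd must be non-negative")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(genome.seq)
    n_pairs = int(round(coverage * L / (2.0 * read_len)))
    lo = 2 * read_len
    pairs = []
    for i in range(n_pairs):
        ins = 0
        while ins < lo or ins > L:
            ins = int(round(rng.normal(insert_mean, insert_sd))) \
                if insert_sd > 0 else insert_mean
            if insert_sd == 0 and (ins < lo or ins > L):
                raise ValueError("degenerate insert incompatible with genome")
        start = int(rng.integers(0, L - ins + 1))
        frag = genome.seq[start:start + ins]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        if error_rate > 0:
            r1 = _add_errors(r1, error_rate, rng)
            r2 = _add_errors(r2, error_rate, rng)
        pairs.append(ReadPair(
            SequenceRecord(f"pair{i}/1", r1, "dna"),
            SequenceRecord(f"pair{i}/2", r2, "dna"),
            insert_size=ins, origin=(start, start + ins),
        ))
    return pairs


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(read)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        chars[i] = rng.choice([b for b in BASES if b != chars[i]])
    return "".join(chars)


@dataclass
class BreakRule:
    """Assembly-break specification: break inside hexamer tandem runs.

    A window qualifies when some hexamer repeats in tandem for at least
    ``min_copies`` copies; the central ``gap_frac`` of the run is removed
    as an assembly gap.
    """

    min_copies: int = 10
    gap_frac: float = 0.5


def _tandem_hexamer_runs(seq: str, min_copies: int) -> list:
    """Maximal intervals where seq[i] == seq[i+6] holds in tandem."""
    n = len(seq)
    runs = []
    i = 0
    min_match = 6 * (min_copies - 1)
    while i < n - 6:
        if seq[i] == seq[i + 6]:
            j = i
            while j < n - 6 and seq[j] == seq[j + 6]:
                j += 1
            if (j - i) >= min_match:
                runs.append((i, j + 6))
            i = j + 1
        else:
            i += 1
    return runs


def fragment_assembly(
    genome: SequenceRecord,
    break_rule: BreakRule | None = None,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[tuple[int, int]]]:
    """Fragment a genome at repeat windows, returning contigs + truth gaps.

    Concatenating contigs and gap sequences in order reconstructs the
    genome exactly; breaks occur only inside qualifying tandem-repeat
    windows.
    """
    if break_rule is None:
        break_rule = BreakRule()
    runs = _tandem_hexamer_runs(genome.seq, break_rule.min_copies)
    gaps = []
    for s, e in runs:
        glen = max(1, int((e - s) * break_rule.gap_frac))
        mid = (s + e) // 2
        gs = max(s, mid - glen // 2)
        gaps.append((gs, min(e, gs + glen)))
    contigs = []
    prev = 0
    k = 1
    for gs, ge in gaps:
        if gs > prev:
            contigs.append(SequenceRecord(
                f"{genome.id}_ctg{k}", genome.seq[prev:gs], "dna"))
            k += 1
        prev = ge
    if prev < len(genome.seq):
        contigs.append(SequenceRecord(
            f"{genome.id}_ctg{k}", genome.seq[prev:], "dna"))
    return contigs, gaps
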