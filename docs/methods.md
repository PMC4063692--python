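# Methods

## The model of an endogenous herpesvirus-like element

The package assumes a roseolovirus-style architecture: a unique
protein-coding region flanked by two direct repeats (DRs), each DR
carrying two telomeric-repeat (TMR) arrays of a hexamer motif from the
TTAGGG satellite family — one perfect array at the terminus that faces the
host chromosome after integration, one imperfect array internal to the DR.
Integration is modelled as a fusion of the host telomeric array with the
virus's terminus-facing perfect array, so the junction is mediated by a
single merged TMR array rather than a base-precise breakpoint. After
integration the element drifts neutrally: substitutions accumulate in the
TMRs (the clock) and disrupt the ORFs (the endogeny signature).

## Synthetic data: what it emulates and what it does not

`evescan.synthetic` generates the study conditions end to end with ground
truth. Defaults reflect the system being emulated: a 49-copy (294 bp)
perfect `TAACCC` array (the size class of roseolovirus DR telomeric
arrays), an imperfect array with ~20% of copies carrying one substitution,
5 synthetic ORFs of 120–260 codons on alternating strands, read pairs of
100 bp with a normal(300, 30) insert truncated below at twice the read
length, and neutral rates 2.2e-9 (mammalian) and 3e-9 (small prosimian)
substitutions/site/year.

Substitution simulation is a per-site continuous-time Markov jump process
under a GTR generator normalised to one expected substitution per site per
unit of `rate × time`, so the expected raw event count for a length-L
sequence is exactly `L·d`; the default model is equal rates with uniform
frequencies, which makes the Jukes–Cantor closed form an external oracle
for the whole chain. Indels are **not** simulated by default — the dating
alignment assumes a colinear ancestor/descendant pair — and sequencing
errors default to zero. ORF-disruption truth is recomputed from the
evolved sequence by codon scanning, never pre-assigned.

Deliberate idealisations: no platform-specific error profiles, no
chimeric reads, no repeat families beyond the TMRs, and assembly
fragmentation is a rule ("break inside hexamer tandem runs of ≥ k
copies"), not an assembler emulation. Sequence flanking generated TMR
arrays is kept free of motif-family hexamers so that array boundaries are
exact ground truth; in real data a chance motif copy adjacent to an array
makes the "true" edge ill-defined at the ±6 bp level. Tests passing on
these data therefore demonstrate algorithmic correctness under the stated
model, not robustness to assembler artefacts or non-neutral repeat
evolution.

## Translated homology search

The search is a tBLASTn analogue without BLAST's seeding heuristics:
candidate regions at desk scale are small enough for exact local
alignment (Smith–Waterman semantics via Biopython's `PairwiseAligner`,
BLOSUM62, gap open −11 / extend −1). Per reading frame, non-overlapping
locally optimal alignments are enumerated by masking each best hit with
`X` and re-aligning (up to 5 hits/frame by default). E-values use
ungapped Karlin–Altschul parameters for BLOSUM62 (λ = 0.3176, K = 0.134)
with `n` the total translated search-space length; this reproduces
BLAST-like ranking without finite-size corrections. An independent
affine-gap DP scorer (`evescan._sw`, numba) exists purely as a
verification oracle and shares no code with the search path.

The shortlist filter keeps hits of ≥ 50 aa with E ≤ 1e-10. The published
phrasing of the E-value direction is ambiguous as printed; the default
discards *non-significant* hits (the other reading discards the best
hits), and `FilterPolicy.discard_significant` flips it for users who want
the literal reading. Reciprocal classification breaks exact score ties
toward `ambiguous`, never silently toward `viral`.

## Junctions and overlaps

TMR arrays are detected as maximal runs of exact motif copies over all six
rotations of both strands, tiled non-overlapping with a phase preference:
after a degraded copy the tiling resumes in the phase of the array start,
so an off-phase chance match cannot shift the frame and distort purity
(purity = intact copies / hexamer windows spanned). The canonical family
representative is the lexicographically smallest rotation over both
strands; orientation is meaningful only up to strand.

A junction is called at an array that separates viral hits from host
evidence; among such candidates the one nearest the host side is reported
(arrays internal to the viral DRs also separate the evidence classes, but
the biological junction is the array the host flank runs into), with the
coordinate at the array edge nearest the viral side. Terminal overlaps
use semi-global alignment (free end gaps on the outer flanks) with
match +2 / mismatch −3 / open −5 / extend −2, both orientations of the
partner tried, and an identity floor of 0.9.

## Dating: conditional GTR likelihood, no halving

The dating statistic is the 4×4 matrix of (ancestor base, observed base)
counts over a window of the observed array anchored at its first and last
intact motif copy, paired positionally against a perfect repeat tiled to
the window length (global alignment engages only when an indel has changed
the length; gap columns are excluded, and fewer than 50 paired sites is an
error).

Two modelling choices matter and were made deliberately:

1. **The likelihood conditions on the ancestor.** A perfect `TAACCC`
   repeat is nothing like a stationary GTR sample — it contains no G at
   all — so the textbook pairwise likelihood `π_i·P_ij(d)` is badly
   misspecified here: the generator row for the absent base is
   data-free, and inflating it drives the π-weighted rate normalisation
   up, which doubles the fitted distance on simulated data. The package
   instead maximises `Σ N_ij log P_ij(d)` (ancestor known, not random)
   and normalises the generator to one expected substitution per site
   under the **ancestor** base composition, so `d` is "expected
   substitutions accumulated per ancestral site" — the quantity a
   known-ancestor divergence measures. On the package's own recovery
   simulations this estimator has |median bias| < 5% across
   d ∈ {0.05, 0.165, 0.3} at 294 sites.
2. **Nested model selection.** The full fit has 9 free parameters
   (log d, five exchangeabilities with GT fixed, three frequency logits;
   L-BFGS-B from the Jukes–Cantor start, Nelder–Mead as fallback). At 294
   sites and low divergence that is over-parameterised and median-biases
   d upward, so the Jukes–Cantor member (closed-form MLE) is used unless
   the full fit improves the log-likelihood by more than its 8 extra
   parameters (AIC). This also makes the equal-rates limit exact: on
   JC-symmetric counts with p = 0.1 the estimate is the closed form
   −(3/4)ln(1 − 4p/3) = 0.10732 to numerical precision.

When optimisation fails entirely the log-det (paralinear) distance is the
tagged fallback; a singular divergence matrix raises a saturation error.

Age conversion is `t = d / r`, **never halved**: the distance runs from a
known ancestral state down one lineage, not between two contemporary
tips. Halving is available only through an explicit `pairwise=True`
escape hatch that flags the estimate as halved so misuse is visible.
Every `AgeEstimate` carries a mandatory warning that telomeric-repeat
evolution may be non-neutral; the package surfaces the caveat rather than
modelling it. Ages are reported at full precision for each supplied rate
(defaults 2.2e-9 and 3e-9 side by side — the rate, not the distance, is
the dominant systematic).

Selecting the window: `date_integration` accepts a `region` restricting
the array search, because the junction array fuses pristine host telomere
with the dated viral repeat and only the viral-side portion carries the
clock — the region normally comes from a junction call, mirroring how an
analyst picks "the viral-side TMR". Its `max_gap` default is 48 bp (eight
motif units): at the divergences being dated, intact copies of a heavily
degraded array sit tens of bases apart, and a small gap ceiling would
fragment the array into its least-diverged islands and bias `d` down.
The residual conditioning bias from anchoring the window on intact copies
is a few percent downward at d ≈ 0.165 and is visible in the acceptance
output (stand-in divergence ≈ 0.154 for a true 0.165).

## Degradation and provenance

Frameshifts are counted by chaining frame-consistent translated hits
along the reference protein (query overlaps up to 10 aa are tolerated as
alignment slop around a breakpoint); each frame change between
consecutive chained segments is one frameshift. Premature stops are `*`
characters inside aligned segments, with a stop aligned at the
reference's terminal position excluded. Provenance rules are
deterministic: endogenous-like when the disrupted-ORF fraction reaches
0.5 (a package default — no quantitative threshold is published for
"nearly all genes") or a host-flank junction exists; exogenous-like only
with zero disruptions, no junction and no transposable-element
acquisition flag (an external input, default false); ambiguous otherwise.

## Targeted scaffolding

Edge extension replaces by-eye curation with explicit thresholds:
overlap ≥ 30 bp at ≤ 2% mismatches, column support ≥ 3 reads, and a
deterministic ambiguity rule — two disagreeing candidate bases that both
reach the support floor stop the walk. Mates of edge-anchored reads are
rescued at the insert-implied offset (verified by alignment before they
vote), which is what makes the method mate-pair rather than overlap-only.
Extension is capped at 400 appended bases per edge so an extended edge
ends *inside* its neighbour, where suffix/prefix linking can see it;
conflicting joins (one edge, two partners) are reported and left
unjoined, circular chains are reported and not constructed, and a
gene-order hint demotes contradictory composites to "flagged" rather than
applying them. With error-free reads and unique sequence the appended
bases match the source template exactly; this is asserted, not assumed.

## Composition features and PCA

Each contig is summarised by coverage, 4 mononucleotide and 16
dinucleotide frequencies (overlapping windows, N excluded) and 4
insert-size statistics over properly paired reads. Features are
standardized before PCA by default because they mix frequency-scale and
base-pair-scale units. Contigs with no aligned pairs are null-flagged and
excluded from the decomposition (and reported). The "viral contigs
cluster together" observation is made testable by a label-permutation
test on the first two components (statistic: flagged-centroid to
bulk-centroid distance; ≥ 999 permutations; seedable); with a single
flagged contig only the distance is reported.

## Problem sizes and numerical conventions

Recovery studies use 294-bp windows with 250–500 replicates per
divergence level, 200 replicates for junction recovery, a 6-kb template
at 30× for scaffolding, and 200 random instances for the alignment
oracle — sizes chosen so the full suite and the acceptance script each
complete in minutes on one core while keeping Monte-Carlo error well
inside the tolerances tested. Coordinates are 0-based half-open
internally; BED output follows the same convention. All stochastic
components accept either a seed or a numpy `Generator`; identical seeds
give identical outputs everywhere.

## Known limitations

- The viral genome model is schematic (HHV6-like layout), not a
  reconstruction of any real exogenous ancestor.
- The dating clock inherits every caveat of neutral-rate dating and one
  more: tandem repeats mutate by slippage as well as substitution, which
  the model does not represent — hence the mandatory warning.
- Reciprocal classification is only as good as the protein sets supplied;
  it does not query remote databases.
- The scaffolder is targeted, not general: it is designed to bridge a
  handful of gaps in a known region, not to improve an assembly at scale.
- Repeat annotation (LINEs/SINEs/ERVs) in flanking sequence is out of
  scope; host evidence on real data is user-supplied.
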