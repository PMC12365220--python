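# Methods

## Background and scope

AAV vector genomes that carry long repeated DNA stretches recombine during
production. The canonical victims are FRET sensors built on CFP/YFP pairs:
both fluorophores descend from the same GFP ancestor, their coding sequences
are >95 % identical at the nucleotide level, and the packaged pools end up as
mixtures of single fluorescent proteins instead of intact sensors.
Abundance-Biased Codon Diversification (ABCD) removes the repeats without
touching the protein: synonymous codons are chosen to minimize an
interaction-energy objective *f* against a reference DNA context, restricted
to codons whose within-family usage fraction in the target organism is at
least a user-chosen *bias*, and excluding forbidden motifs (restriction
sites, vector elements such as ITRs).

This package implements the designer, the repeat diagnostics used to audit
FP pairs (longest identical stretch, maximal-exact-match histograms, dot
plots), the objective itself, a long-read chimera analysis for quantifying
recombination in sequenced pools, and seeded synthetic-data generators so
that everything is testable without downloads.

## The objective *f*

The risk driver is hybridization between repeated stretches. For a construct
`C = context ‖ seq` we score every *register* — every relative offset `d > 0`
of `C` slid against a second copy of itself. Within a register, perfectly
matched runs of at least `m_min` bases (default 6) can nucleate a duplex.
Two nucleating runs on the same register may pair within a single duplex if
the interior loop between them is worth bridging: a loop of `g` unpaired
bases costs `loop_open + loop_per_nt · g` kcal/mol (defaults 1.0 and 0.5),
and runs more than `max_loop = 50` bases apart are never bridged. Each group
of bridgeable runs contributes the energy of its *optimal contiguous
sub-chain* (found by a minimum-sum subarray scan): matched runs add their
nearest-neighbor stacking free energies (unified ΔG°37 dinucleotide table),
bridged gaps add their loop cost, and unprofitable extensions are simply not
zipped. Matches shorter than the seed never contribute on their own — a
register that is merely half-right everywhere is not a duplex.

The objective aggregates these pairing events Boltzmann-style:

    f = Σ_blocks exp(−E_block / rt),      log10 f computed exactly in log space

Only blocks involving `seq` count; repeats wholly inside a fixed context are
the context's own business. `log10 f` is reported even when `f` exceeds the
double-precision ceiling (~1e308), in which case the score is flagged
`overflowed` — the regime near-identical FP pairs occupy.

### Parameter choices

* `m_min = 6` — shortest stretch treated as able to nucleate pairing; also
  the seed length for run enumeration.
* Unified nearest-neighbor ΔG°37 stack table — the standard parameterization
  for DNA duplex stability; average stack ≈ −1.4 kcal/mol.
* `rt = 1.0` kcal/mol — deliberately a free scale of the score, not the
  thermodynamic RT at 310 K. It fixes how many decades of *f* one matched
  stack is worth (≈ 0.6). The value was chosen, together with the loop-cost
  constants, by a design-time analysis of the three regimes the score must
  separate: a fully diversified ~700-bp CDS carries only scattered chance
  hexamers (log10 f ≈ 4–6), cross-organism FP pairs (~55 % identity) score
  finite and tens of decades higher, and ≥95 %-identity pairs — whose
  homologous register zips essentially end to end through point-mismatch
  loops — exceed 10^308. The original scrambling literature does not publish
  its energy parameterization, so printed *f* values from other
  implementations are reproduced in regime, not digit by digit.
* `loop_open = 1.0`, `loop_per_nt = 0.5`, `max_loop = 50` — point-mismatch
  loops (the texture of near-identical pairs) cost ~1.5 kcal/mol and never
  interrupt zipping, while bridging the 10–60-base gaps between the small
  forced islands of a well-diversified sequence does not pay.

`duplex_delta_g` applies the same chaining rule to a single end-to-end
alignment of two equal-length windows and returns the optimal duplex energy,
or `None` below the seed gate.

## The search

Synonymous design is combinatorial (~10^100 encodings for a 239-residue
protein), and *f* is dominated by the longest and densest shared runs. The
search therefore minimizes a cheap exact surrogate — the weighted number of
shared q-gram pairs over `context ‖ candidate` for q ∈ {6, 8, 10, 12, 14},
with weight rising tenfold per 2 bp — maintained incrementally under
append/pop/substitute edits (incremental bookkeeping is asserted equal to a
from-scratch rebuild in the test suite). Four phases:

1. **Greedy construction** left to right, choosing per slot the allowed codon
   with the smallest surrogate increment; forbidden motifs (both strands,
   including motifs spanning the context junction) veto candidates, with
   bounded backtracking. Equal scores resolve by higher family fraction, then
   alphabetically.
2. **Simulated annealing**: random synonymous swaps under geometric cooling,
   `budget` moves (default 2000).
3. **Repair**: any residual shared run longer than `m_min + 2` is re-broken
   by the best synonymous substitution inside it.
4. **Polish**: greedy coordinate descent on the *true* objective. The
   surrogate counts shared grams but cannot see that runs concentrated on one
   register chain into a single exponentially-weighted block; each polish
   round targets the worst block and applies the substitution (ranked by a
   local recomputation at that register, verified by a full `objective_f`
   recomputation) that lowers log10 f the most.

All randomness flows from the single task seed; identical tasks reproduce
byte-identical output. Reported scores are always full recomputations; the
surrogate never appears in results.

When a forbidden motif is unavoidable (for example, both mouse-preferred
arginine codons begin with `A`, so a reference context ending in `…CTGTAC`
forces a BsrGI site across the junction whatever the designer does), the
search raises a diagnostic error naming the motif instead of emitting a
violating sequence.

Chained diversification for multi-FP constructs simply grows the reference:
target *i* is designed against `shared_reference ‖ outputs 1..i−1`, and the
pairwise longest-identical-stretch matrix over all sequences is reported.

## Codon-usage handling

"Relative abundance" is the within-family fraction (per-thousand values are
normalized per synonymous family); this is the only reading under which
biases of 0–20 % are meaningful. At any bias every residue keeps at least
its most abundant codon (fallback, logged). A mouse usage table ships with
the package (approximate published mouse frequencies; the within-family
ranking is the operative content). Of note, at 20 % bias the mouse table
leaves leucine a single codon (CTC sits at a family fraction of 0.199), and
methionine and tryptophan are always single-codon.

## Synthetic data

`make_homolog_pair` emulates FP FRET pairs: a random protein is encoded with
usage-weighted codons, then the second copy diverges by synonymous *point*
edits first (the mutational texture separating GFP-derived variants) and by
whole-codon replacements only when the identity target is below synonymous
reach. Targets are met within ±1 %. Fixture proteins are drawn at
globular-protein residue frequencies without Leu/Met/Trp triplets ("fp"
composition): real FP substrates contain no such triplets, and under
abundance biasing they would be stretches that *no* synonymous method can
alter (an 11-bp forced repeat for an L/L/L run at 20 % bias).
`make_random_protein` also offers the uniform-composition mode used by the
large constraint-audit test.

What the generators do **not** emulate: real FP pairs' specific GC content
and codon autocorrelation, linker/cloning scars (the stretches that inflated
the Laconic pair's score in practice), and long-read indel error profiles.
Passing tests therefore demonstrate the algorithmic contracts under
controlled conditions, not digit-level agreement with any particular
published construct.

## Chimera analysis

Reads are anchored by two flanking stretches (Hamming matching, unique hit
per anchor, reverse-complement rescue), the insert between anchors is
extracted, and identical inserts are grouped. Groups at the single-FP length
are called letter by letter at the discriminating positions (donor base →
`C`, acceptor base → `Y`); any other base marks a sequencing error and
discards the whole group. The count-weighted fraction of `Y` at each
position is the cumulative probability that recombination occurred before
that position; a least-squares line and R² summarize its shape (linear with
slope ≈ 1/n under uniform breakpoints). The chimeric fraction is the share
of anchored inserts at single-FP length. Indel-bearing reads fall out of the
length filter and are counted only in that denominator — a documented
limitation of alignment-free calling. A pure-donor control defines a
per-position error floor that can be subtracted (clamped at zero). The
simulator emits the matching pools: chimera `donor[:b] ‖ acceptor[b:]` with
probability ρ (breakpoint uniform or custom-weighted), intact construct
otherwise, wrapped in anchors and random pads, i.i.d. substitution errors,
half the reads reverse-complemented, fully deterministic per seed.

## Problem sizes and numerical choices

Tests run at the sizes the contracts name: 1000 design runs at 50–300
residues (light refinement budget, since that audit concerns constraints,
not score quality), the 239-residue bias sweep and three-way chain at the
default budget, 500 oracle comparisons at ≤200 bp, and 10,000 simulated
reads for the chimera recovery. The three-way chain is exercised at 10 %
bias: with three sequences drawn from two-codon families, matching one
predecessor somewhere is a pigeonhole certainty, and higher biases make this
dense — the same effect that drove the choice of a 15 % (not 20 %) bias for
the triple-FP construct this workflow targets.

Ties in the search resolve by family fraction then codon alphabetically;
log-sum-exp accumulation keeps `log10 f` exact through the overflow regime;
the −∞ sentinel (no pairing event anywhere) serializes as `null`.

## Known limitations

* Proteins with periodic leucine-pair clusters (leucine-rich-repeat-like)
  retain forced repeats at 20 % bias that place a floor of roughly 1e8–1e10
  on *f* — the same ceiling reported for triple-FP design at high bias. The
  designer still minimizes the repeat structure; the floor is a property of
  the codon table, not the search.
* Anchor matching is substitution-only; reads whose anchors are disrupted by
  indels are dropped (counted), and circularly permuted acceptors are out of
  scope for position calling.
* The energy parameterization is a surrogate calibrated to regimes (see
  above); absolute *f* values are comparable within this implementation
  only.
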