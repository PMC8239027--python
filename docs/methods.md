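# Methods

## Problem setting and model

A chromosome-scale assembly built by long-read assembly plus Hi-C
scaffolding contains two characteristic defect classes: *misjoins*
(sequence from different chromosomal loci joined on one scaffold, an
artefact of proximity-ligation scaffolding) and *N-gaps* (unresolved
sequence between contigs).  Independent de novo assemblies of the same
reads have different contiguity profiles: a region fragmented in one
assembly is frequently one contiguous contig in another.  `scaffmend`
formalizes the consensus logic this enables:

- **Check A (gap proximity).** Scaffolding joins occur across gaps, so a
  structural disagreement is treated as a candidate misjoin only when an
  N-tract lies within `gap_window` (default 20 kb) of the junction.  The
  window absorbs alignment-boundary slack; whether the gap must sit
  strictly inside the disputed block is not knowable from first
  principles, so proximity is used and the window is configurable.
- **Check B (consensus).** At least two alternates must be discrepant
  with the base *and* mutually consistent.  "Mutually consistent" is
  operationalized as: their discrepancies fall in one cluster (within
  `merge_window`, default 20 kb) and have the same class — different
  donor contig, flipped orientation, reversed order, or a
  donor-coordinate jump exceeding `jump_tol` (default 10 kb) relative to
  the base gap.  Order and orientation of local blocks is exactly what a
  manual dot-plot inspection evaluates; the class labels discretize it.

A junction where one alternate's contig simply ends and another begins
asserts nothing about adjacency (it is an ordinary contig break), so it
is not counted as a discrepancy; a contig whose continuation maps
elsewhere is (`end_slack`, default 500 bp, tolerates unaligned termini).

## Alignment

The built-in aligner is the classical seed-and-chain design operating at
the block level; there is deliberately no base-level (CIGAR) alignment,
because the unit of reconciliation is the block and edit boundaries snap
to anchors, where base and donor agree exactly.

1. Window minimizers (k = 15, window = 10) of the alternate contigs are
   indexed by exact 2-bit canonical code — code equality implies sequence
   identity, so anchors are exact matches by construction.  Codes
   occurring more than `max_occ` = 50 times are dropped as repetitive.
2. Base minimizers are looked up; co-diagonal hits at most k apart merge
   into maximal exact-match runs (overlapping exact k-mer matches on one
   diagonal imply the union is an exact match).  Runs contained in a
   longer run on both axes are pruned as tandem-repeat shadows.
3. Runs are chained by sparse dynamic programming: successors must
   advance on both axes (starts *and* ends — an anchor contained in a
   longer one is not a successor) with per-axis start-to-end gap at most
   `gap_limit` (10 kb); a chain's score is its summed anchor length, and
   chains scoring under `min_block_len` (500 bp) are discarded.
4. Blocks overlapping on the base are resolved best-score-first, trimming
   lower-score blocks at their edges (ties: longer block, then smaller
   contig id); a block that would be split by an internal overlap is
   dropped.

Defaults were chosen to resolve the 100 kb-scale contigs of the synthetic
scenarios; all are configurable, and pre-computed PAF from any external
aligner can be substituted (PAF blocks anchor at their endpoints).

### Cut-point trust

Isolated seed-size (15 bp) matches arise by chance roughly once per
10⁹ base pairs compared; chaining can absorb one at a chain edge.  Such
an anchor is not a safe coordinate reference, so every consumer of cut
points (junction classification, replacement and fill boundaries) uses
only anchors of length ≥ `min_event_anchor` (50 bp).  Exact-match runs
flanking real junctions are kilobases long, so this costs nothing; it
protects against splicing at a spurious coordinate.

## Edits

**Block replacement.** For an actionable call and one agreeing alternate,
the repair interval runs from the inner edge of the last trusted anchor
upstream of the junction to the first trusted anchor of the nearest
downstream block of the *same* donor contig and strand (searched up to
`max_replace_span`, 500 kb; a mirrored upstream search covers the
junction's right edge).  The base interval is replaced by the donor
interval between the corresponding donor coordinates
(reverse-complemented for '−' donors).  An empty donor interval is a
valid pure excision — the case where the disputed sequence's flanks are
directly adjacent in the donor.  The donor is drawn by seeded RNG among
the agreeing alternates that can supply an interval, and the draw index
is recorded in the edit.  Edits are collected per scaffold, processed
largest-evidence-first (ties leftmost), overlap-skipped, and applied
right-to-left so pre-edit coordinates stay valid.

**Gap fill.** After replacement the assembly is re-aligned.  A gap is
fillable by an alternate iff a single block spans it with ≥ `flank`
(5 kb) on both sides, trusted anchors lie within `max_anchor_dist` (2 kb)
of the gap edges, and the donor interval contains no N.  One eligible
alternate is drawn by seeded RNG.  Consecutive gaps whose fill intervals
overlap under the same donor block merge into one combined edit;
conflicting-donor overlaps keep the leftmost fill.

**Merge.** Scaffolds ≥ `min_merge_len` (10 Mb; lowered in tests) merge
when ≥ `min_merge_evidence` (2) alternates each have one contig whose
blocks cover a terminal window (50 kb) of one end of each scaffold,
disjointly and collinearly — walking the contig must exit the first
scaffold through its touched end and enter the second through its touched
end, which also resolves the orientation.  Conflicting evidence for one
scaffold end vetoes its merges.  Halves are joined across
`join_gap_len` = 100 N (the join length is a convention, not an
estimate).

Every edit updates both the sequence and a per-scaffold component list
(source assembly, interval, strand, or N-run), serialized as AGP v2.1;
replaying the components against the source assemblies reconstructs the
hybrid byte-exactly, which the test suite asserts.

## Validation

BAC-end style pairs are concordant iff both ends map with
mapq ≥ `min_mapq` to one scaffold, inward-facing forward–reverse, with
outer insert inside [`min_insert`, `max_insert`] (defaults 20 kb /
300 kb bracket a BAC insert distribution generously; the synthetic checks
use mean ± 4 sd of the simulated distribution, which is how the
simulated pairs are constructed).  FF/RR orientation is reported as
`same_strand`, outward-facing RF as `outward_facing`.  The before/after
report counts verdicts per assembly and lists every pair whose verdict
changed.

## The simulator and what it does (not) show

`SimConfig` defaults define the standard scenario: three 1 Mb
chromosomes (GC 0.41, 5% exact tandem repeats of 150 bp units), a base
assembly of 11 fragments per chromosome re-joined across 100–2000 bp
N-gaps (30 gaps), five injected misjoins, three alternates of ~4
fragments per chromosome, 1,000 BAC pairs of 150 ± 20 kb insert
(truncated at ± 4 sd so the sampling support coincides with the
validation window and a discordant verdict is always structural).  Sizes
were chosen so that one scenario exercises every code path at desk scale.

Misjoins are *insertion-type*: a fragment of another chromosome is
spliced, gap-flanked, between two truly adjacent fragments, and removed
from its source (whose neighbours join across a gap).  This is the
cross-chromosome error mode that block replacement can actually repair
with a contiguous donor — the wrongly placed sequence is excised, and the
deletion it left behind is re-inserted from a spanning donor contig.
Inversions strand-flip a fragment in place.  Alternates are independent
fragmentations of the truth rather than re-assemblies: that captures
exactly the property the method exploits (different contiguity, shared
sequence) without simulating assemblers.

Two constraints realize the method's stated preconditions rather than
tuning anything: events are placed only where ≥ `min_spanning_alts` (2)
alternates are contiguous across the affected span (the consensus check
and the repair both require a spanning donor — an assembly problem no
consensus method can solve has no donor anywhere), and no fragment cut
falls within 2 kb of a tandem-repeat tract, because anchor coordinates
inside a tandem array are ambiguous by multiples of the unit length and a
junction planted there can legitimately heal one unit short
(repeat-boundary collapse — a known limitation of anchor-based splicing,
shared with real pipelines).

BAC pairs are placed onto assemblies by exact liftover through the truth
records (no aligner); an end crossing a liftover boundary is unmapped.
Hybrid truth records are composed through the edit provenance, with
truth-contiguous neighbours merged so a seamless repair leaves no
boundary.

What passing the synthetic suite does **not** show: robustness to
base-level divergence between assemblies (the alternates are exact truth
slices by default; a per-base error rate is available but zero),
assembler-specific artefacts (collapsed segmental duplications, chimeric
contigs beyond the optional chimera flag), real repeat landscapes, or
performance at multi-gigabase scale.  The defaults are study conditions,
not claims about any particular genome.

## Numerical and reproducibility choices

- Coordinates are 0-based half-open everywhere internally; AGP output is
  1-based inclusive per the standard.
- N(X) uses the ceiling convention: the sequence whose cumulative sum
  reaches the X% boundary is included.  N-tract counting uses
  `min_gap_len` = 1 (every N run counts); an NCBI-style minimum of 10 is
  a flag away.
- Soft-masking is discarded on read (uppercased); the method is
  mask-agnostic.  U is normalized to T; non-N IUPAC codes are kept and
  warned about (they never match an anchor).
- All randomness flows from one integer seed: the simulator derives
  per-stage substreams from it, and donor draws use a seeded RNG whose
  draw index is stored in the edit record.  Identical inputs and seed
  give byte-identical FASTA, AGP and reports; the test suite asserts
  this.
- Degenerate inputs: empty assemblies and assemblies of all-N scaffolds
  error or warn explicitly; a donor interval of length zero is applied
  as an excision; zero-length provenance components are elided.

## Known limitations

- Replacement boundaries snap to exact-match anchors; in diverged real
  data anchors shorten and boundary slack grows with divergence.
- Tandem-repeat boundaries can heal collapsed or expanded by one unit.
- The junction classifier reports the dominant agreeing class only; a
  site where alternates disagree about the *kind* of discrepancy keeps
  the larger faction and may under-count agreement.
- Merging is one round of pairwise joins; chains of three or more
  scaffolds merge only on a re-run.
- No consensus polishing is performed: donor-derived intervals are
  emitted verbatim and are candidates for downstream polishing, which is
  out of scope here.
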