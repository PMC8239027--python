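# scaffmend

Consensus-based genome assembly reconciliation: detect and repair
scaffolding misjoins in a *base* assembly by cross-checking two or more
*alternate* de novo assemblies of the same genome, fill N-gaps from
gap-free alternate intervals, merge scaffolds with alternate-attested
adjacency, and validate the result with BAC-end pair concordance.

## Who this is for

Genome assembly projects routinely produce one "best" long-read assembly,
scaffold it to chromosome scale with Hi-C, and discard the assemblies
produced by the other assemblers they tried.  Those discarded assemblies
are evidence: a region broken into several pieces by one assembler is
often a single contiguous contig in another.  `scaffmend` turns that
contiguity complementarity into an automated correction step, the way
chromosome-scale non-human-primate assembly projects have done manually
with dot plots.

## The method

Let `B` be the base assembly and `A₁ … Aₙ` (n ≥ 2) alternates.  Each `Aᵢ`
is aligned to `B`, giving strand-aware **alignment blocks** (chained
minimizer anchors; or PAF from any external aligner).  At every junction
between adjacent blocks of one alternate, a discrepancy is recorded when
the blocks map to different alternate contigs, in flipped orientation, in
reversed order, or with a donor-coordinate jump inconsistent with the base
gap.  Discrepancies from different alternates within 20 kb cluster into a
**breakpoint call**, which is *actionable* iff

1. an N-gap lies within `gap_window` of the junction (scaffolding joins
   sit at gaps), and
2. at least two alternates are discrepant with the base **and** mutually
   consistent (same discrepancy class at the same junction).

For each actionable call the base interval between the nearest *shared
anchors* — positions where base and donor agree exactly — is replaced by
the corresponding interval of one agreeing alternate, chosen by seeded
RNG and recorded, yielding a **hybrid assembly**.  The same block
machinery then fills each gap spanned gap-free by an alternate with
≥ 5 kb aligned flanks, and optionally merges scaffold pairs whose ends are
bridged collinearly by single contigs of ≥ 2 alternates.  Every edit is an
`EditRecord` with full coordinate provenance, and the hybrid carries an
AGP v2.1 component map, so every output base is attributable to its
source assembly.

Validation mirrors the classic BAC-end check: large-insert read pairs are
classified concordant (one scaffold, inward-facing FR, insert within
bounds) or discordant, and counts are compared before vs after
reconciliation.

The `simulator` module generates seeded truth genomes, corrupted base
assemblies (gaps, interchromosomal misjoins, inversions), independent
alternates and BAC-end pairs with machine-readable truth records, so
every claim above is checkable exactly, without any external aligner.

## Worked example

`examples/03_reconcile_pipeline.py` simulates two 300 kb chromosomes,
fragments them into a gapped base assembly with one injected
interchromosomal misjoin plus three independent alternates, and runs the
pipeline:

```
breakpoints called     3
actionable (gap + >=2) 3
blocks replaced        2
gaps filled            4 (2756 bp of N removed)
gaps remaining         1 (were 8)

per-scaffold truth liftover after reconciliation:
  scaffold_1: collinear=True
  scaffold_2: collinear=True
truth bases unaccounted for: 0
```

Three junctions are called (the two edges of the intruding fragment on
its wrong chromosome, and the deletion-type junction it left behind);
both repairs apply; gap filling then removes 2.8 kb of N.  Collinear
liftover with zero missing bases means the hybrid equals the truth up to
the remaining (unspannable) gap.  `examples/04_bac_end_validation.py`
shows the matching validation signature on 500 simulated BAC pairs:

```
verdict        before  after  delta
concordant        354    499   +145
discordant        145      0   -145
```

The other examples cover contiguity statistics (N50 / N(X) curves / gap
counts) and the aligner's dot-plot export.

## Command line

A thin CLI wraps the library:

```bash
scaffmend simulate -o sim --seed 7
scaffmend stats sim/base.fa -o stats
scaffmend reconcile sim/base.fa -a sim/alt1.fa -a sim/alt2.fa -a sim/alt3.fa \
    --seed 7 -o out        # hybrid.fa, hybrid.agp, report.json, breakpoints.bed
scaffmend validate-pairs before.tsv after.tsv -o delta
```

Every run writes a `manifest.json` (input checksums, parameters, seed,
version), so results are reproducible from the manifest alone.

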