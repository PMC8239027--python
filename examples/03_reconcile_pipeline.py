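"""The full consensus-reconciliation pipeline on a simulated scenario.

A truth genome is fragmented into a gapped base assembly with one injected
interchromosomal misjoin, plus three independent gap-free alternates.  The
pipeline calls breakpoints where at least two alternates agree against the
base at a gap, replaces the misjoined blocks with donor sequence, fills
the remaining N gaps, and reports every edit with provenance.  The truth
records let us verify the repair exactly.
"""

import collections

import scaffmend as sm

cfg = sm.SimConfig(seed=7, n_chromosomes=2, chromosome_length=300_000,
                   base_n_fragments=5, n_misjoins=1, alt_n_fragments=3,
                   bac_n_pairs=0, min_fragment_len=20_000)
truth = sm.generate_truth(cfg)
base, record = sm.corrupt_to_base(truth, cfg)
altpairs = sm.make_alternates(truth, cfg)
alts = {a.name: a for a, _ in altpairs}

hybrid, report, calls = sm.reconcile_pipeline(base, alts, seed=7)

print(f"breakpoints called     {report.n_breakpoints_called}")
print(f"actionable (gap + >=2) {report.n_actionable}")
print(f"blocks replaced        {report.n_blocks_replaced}")
print(f"gaps filled            {report.n_gaps_filled} "
      f"({report.filled_gap_total_length} bp of N removed)")
print(f"gaps remaining         {len(sm.find_gaps(hybrid))} "
      f"(were {len(sm.find_gaps(base))})")

records = {"base": record, **{a.name: r for a, r in altpairs}}
hrec = sm.compose_truth_record(hybrid, records)
cover = collections.Counter()
for sid, segs in hrec.segments.items():
    for s in segs:
        if s.kind == "seq":
            cover[s.chrom] += s.length
print("\nper-scaffold truth liftover after reconciliation:")
for s in hybrid:
    print(f"  {s.id}: collinear={hrec.is_collinear(s.id)}")
missing = sum(c.length - cover[c.id] for c in truth)
print(f"truth bases unaccounted for: {missing}")
print("\nCollinear scaffolds and zero missing bases mean the injected")
print("misjoin was excised, its fragment returned to its home chromosome,")
print("and the gap fills restored the exact truth sequence.")
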