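"""Shared fixtures: a small single-seed scenario for unit-level checks and
the 20-seed standard scenario sweep used by the acceptance tests."""

import collections

import pytest

import scaffmend as sm
from scaffmend.simulator import _alternate_cuts
from scaffmend.validation import classify_pairs, compare_assemblies

STANDARD_SEEDS = list(range(1, 21))


def small_config(seed=7, **kw):
    """A reduced scenario for fast unit tests (two 300 kb chromosomes)."""
    defaults = dict(
        seed=seed, n_chromosomes=2, chromosome_length=300_000,
        base_n_fragments=5, n_misjoins=1, alt_n_fragments=3,
        bac_n_pairs=200, bac_insert_mean=60_000, bac_insert_sd=8_000,
        min_fragment_len=20_000,
    )
    defaults.update(kw)
    return sm.SimConfig(**defaults)


def build_scenario(cfg):
    truth = sm.generate_truth(cfg)
    base, record = sm.corrupt_to_base(truth, cfg)
    altpairs = sm.make_alternates(truth, cfg)
    alts = {a.name: a for a, _ in altpairs}
    records = {"base": record, **{a.name: r for a, r in altpairs}}
    return dict(cfg=cfg, truth=truth, base=base, record=record,
                alts=alts, records=records)


@pytest.fixture(scope="session")
def small_scenario():
    return build_scenario(small_config())


def run_standard_seed(seed):
    """Run the full standard scenario for one seed and distil the
    measurements the acceptance criteria need."""
    cfg = sm.SimConfig(seed=seed)
    sc = build_scenario(cfg)
    truth, base, record = sc["truth"], sc["base"], sc["record"]
    alts, records = sc["alts"], sc["records"]

    hybrid, report, calls = sm.reconcile_pipeline(base, alts, seed=seed)
    hrec = sm.compose_truth_record(hybrid, records)

    cover = collections.Counter()
    for sid, segs in hrec.segments.items():
        for s in segs:
            if s.kind == "seq":
                cover[s.chrom] += s.length
    missing_bp = sum(c.length - cover[c.id] for c in truth)
    collinear = all(hrec.is_collinear(s.id) for s in hybrid)

    # per-misjoin: actionable call within the cluster window of a junction gap
    actionable = [c for c in calls if c.actionable]
    mj_called = []
    for mj in record.misjoins:
        hits = []
        for gap in mj["junction_gaps"] + [mj["source_gap"]]:
            if gap is None:
                continue
            sid = mj["target_scaffold"] if gap in mj["junction_gaps"] else mj["source_scaffold"]
            mid = (gap[0] + gap[1]) // 2
            hits.append(any(c.base_id == sid and abs(c.position - mid) <= 20_000
                            for c in actionable))
        mj_called.append(all(hits))

    # replaced intervals: donor content is an exact truth substring
    truth_match = []
    for e in report.edits:
        if e.kind != "block_replacement" or e.inserted_length == 0:
            continue
        donor = alts[e.donor_assembly][e.donor_id].sequence[e.donor_start:e.donor_end]
        seg = records[e.donor_assembly].segments[e.donor_id][0]
        t = truth[seg.chrom].sequence[seg.t_start + e.donor_start:
                                      seg.t_start + e.donor_end]
        truth_match.append(donor == t)

    # gap accounting: truth-fillable ordinary junctions
    event_gaps = set()
    for mj in record.misjoins:
        for g in mj["junction_gaps"] + [mj["source_gap"]]:
            if g:
                event_gaps.add(tuple(g))
    hindex = hrec.truth_index()
    ordinary, fillable, healed = 0, 0, 0
    flank = sm.ReconcileParams().flank
    alt_cuts = [_alternate_cuts(truth, cfg, ai) for ai in range(cfg.n_alternates)]
    for sid, segs in record.segments.items():
        pos = 0
        for prev, seg in zip(segs, segs[1:]):
            pos += prev.length
            if seg.kind != "gap" or (pos, pos + seg.length) in event_gaps:
                continue
            if prev.kind != "seq" or prev.strand != "+":
                continue
            t = prev.t_end  # truth junction position
            ordinary += 1
            spanned = any(all(abs(c - t) > flank + 500 for c in cuts[prev.chrom])
                          for cuts in alt_cuts)
            if spanned:
                fillable += 1
                if sm.map_truth_interval(hindex, prev.chrom, t - 50, t + 50):
                    healed += 1

    gaps_before = sm.find_gaps(base)
    gaps_after = sm.find_gaps(hybrid)

    # BAC-end concordance, before vs after, via exact projection
    placements = sm.sample_bac_pairs(truth, cfg)
    lo = cfg.bac_insert_mean - 4 * cfg.bac_insert_sd
    hi = cfg.bac_insert_mean + 4 * cfg.bac_insert_sd
    before = classify_pairs(sm.project_pairs(placements, record), lo, hi)
    after = classify_pairs(sm.project_pairs(placements, hrec), lo, hi)
    delta = compare_assemblies(before, after)
    straddlers = [c.pair_id for c in before if c.reason == "different_scaffold"]
    amap = {c.pair_id: c for c in after}
    flipped = sum(amap[p].verdict == "concordant" for p in straddlers)

    return dict(
        seed=seed, n_misjoins=len(record.misjoins), mj_called=mj_called,
        collinear=collinear, missing_bp=missing_bp,
        truth_match=truth_match, report=report,
        n_gaps_before=len(gaps_before), n_gaps_after=len(gaps_after),
        n_len_before=sum(g.length for g in gaps_before),
        n_len_after=sum(g.length for g in gaps_after),
        contig_n50_before=sm.compute_stats(base).contig_n50,
        contig_n50_after=sm.compute_stats(hybrid).contig_n50,
        ordinary=ordinary, fillable=fillable, healed=healed,
        delta=delta.deltas, n_straddlers=len(straddlers), n_flipped=flipped,
    )


@pytest.fixture(scope="session")
def standard_runs():
    return [run_standard_seed(seed) for seed in STANDARD_SEEDS]
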