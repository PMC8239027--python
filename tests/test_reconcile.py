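"""Breakpoint calling, block replacement, gap filling, merging, pipeline."""

import random

import pytest

import scaffmend as sm
import scaffmend.reconcile as rc
from scaffmend.alignment import align_to_all
from scaffmend.assembly_io import (
    AssemblySet, Scaffold, reverse_complement, render_components,
)
from conftest import small_config, build_scenario


def _rand_seq(n, seed):
    return "".join(random.Random(seed).choices("ACGT", k=n))


@pytest.fixture(scope="module")
def pipeline_run(small_scenario):
    sc = small_scenario
    hybrid, report, calls = sm.reconcile_pipeline(
        sc["base"], sc["alts"], seed=sc["cfg"].seed)
    return sc, hybrid, report, calls


class TestCallBreakpoints:
    def test_consistent_junctions_yield_no_call(self):
        seq = _rand_seq(80_000, 5)
        base = AssemblySet("base", [Scaffold("s", seq[:40_000] + "N" * 500 + seq[40_000:])])
        alts = {f"alt{i}": AssemblySet(f"alt{i}", [Scaffold("c", seq)]) for i in (1, 2)}
        aligns = align_to_all(base, alts)
        calls = rc.call_breakpoints(base, sm.find_gaps(base), aligns)
        assert [c for c in calls if c.actionable] == []

    def test_misjoin_produces_clustered_actionable_call(self, pipeline_run):
        sc, _, _, calls = pipeline_run
        record = sc["record"]
        actionable = [c for c in calls if c.actionable]
        for mj in record.misjoins:
            for gap in mj["junction_gaps"]:
                mid = (gap[0] + gap[1]) // 2
                assert any(c.base_id == mj["target_scaffold"]
                           and abs(c.position - mid) <= 20_000 for c in actionable), mj
        assert all(c.n_discrepant_agreeing >= 2 for c in actionable)
        assert all(c.gap_nearby for c in actionable)

    def test_single_discrepant_alternate_not_actionable(self):
        seq = _rand_seq(120_000, 6)
        # base carries a 30 kb inversion in the middle; one alternate matches
        # the truth (discrepant with base), two match the base (consistent)
        inv = seq[:45_000] + "N" * 300 + reverse_complement(seq[45_300:75_000]) \
            + "N" * 300 + seq[75_300:]
        base = AssemblySet("base", [Scaffold("s", inv)])
        alts = {
            "alt1": AssemblySet("alt1", [Scaffold("c", seq)]),
            "alt2": AssemblySet("alt2", [Scaffold("c", inv.replace("N", "A"))]),
            "alt3": AssemblySet("alt3", [Scaffold("c", inv.replace("N", "C"))]),
        }
        aligns = align_to_all(base, alts)
        calls = rc.call_breakpoints(base, sm.find_gaps(base), aligns)
        emitted = [c for c in calls if "alt1" in c.agreeing_alts]
        assert emitted, "the lone truth-matching alternate should be discrepant"
        assert all(not c.actionable for c in emitted)

    def test_unknown_base_id_raises(self, small_scenario):
        sc = small_scenario
        aligns = align_to_all(sc["base"], sc["alts"])
        for blocks in aligns.values():
            for b in blocks:
                b.base_id = "nope"
        with pytest.raises(ValueError, match="nope"):
            rc.call_breakpoints(sc["base"], [], aligns)


class TestBlockReplacement:
    def test_no_actionable_calls_is_identity(self, small_scenario):
        sc = small_scenario
        base = sc["base"]
        aligns = align_to_all(base, sc["alts"])
        out, edits = rc.apply_block_replacements(base, aligns, [], 0,
                                                 alt_assemblies=sc["alts"])
        assert edits == []
        assert all(out[s.id].sequence == s.sequence for s in base)

    def test_replaced_intervals_are_truth_sequence(self, pipeline_run):
        sc, hybrid, report, _ = pipeline_run
        truth, records = sc["truth"], sc["records"]
        checked = 0
        for e in report.edits:
            if e.kind != "block_replacement" or e.inserted_length == 0:
                continue
            donor = sc["alts"][e.donor_assembly][e.donor_id] \
                .sequence[e.donor_start:e.donor_end]
            seg = records[e.donor_assembly].segments[e.donor_id][0]
            expect = truth[seg.chrom].sequence[seg.t_start + e.donor_start:
                                               seg.t_start + e.donor_end]
            if e.donor_strand == "-":
                donor = reverse_complement(donor)
                expect = reverse_complement(expect)
            assert donor == expect
            checked += 1
        assert checked > 0

    def test_conservation_by_provenance_replay(self, pipeline_run):
        sc, hybrid, _, _ = pipeline_run
        sources = {"base": sc["base"], **sc["alts"]}
        for s in hybrid:
            assert render_components(hybrid.provenance[s.id], sources) == s.sequence


def _gap_fill_fixture(strand="+"):
    """Base with one gap; a single alternate contig spanning it (optionally
    reverse-complemented)."""
    seq = _rand_seq(60_000, 9)
    base = AssemblySet("base", [Scaffold("s", seq[:30_000] + "N" * 400 + seq[30_000:])])
    contig = seq if strand == "+" else reverse_complement(seq)
    alt = AssemblySet("alt1", [Scaffold("c", contig)])
    aligns = align_to_all(base, {"alt1": alt})
    return base, {"alt1": alt}, aligns, seq


class TestFillGaps:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_fill_restores_truth_either_strand(self, strand):
        base, alts, aligns, seq = _gap_fill_fixture(strand)
        out, edits, summary = rc.fill_gaps(base, sm.find_gaps(base), aligns,
                                           rng_seed=1, alt_assemblies=alts)
        assert summary["n_gaps_filled"] == 1
        assert out["s"].sequence == seq
        assert edits[0].donor_strand == strand

    def test_donor_with_n_not_used(self):
        seq = _rand_seq(60_000, 10)
        base = AssemblySet("base", [Scaffold("s", seq[:30_000] + "N" * 400 + seq[30_000:])])
        # donor N tract straddles the junction, so any donor interval
        # bridging the base gap necessarily contains N
        gappy = seq[:29_995] + "N" * 10 + seq[30_005:]
        alts = {"alt1": AssemblySet("alt1", [Scaffold("c", gappy)])}
        aligns = align_to_all(base, alts)
        out, edits, summary = rc.fill_gaps(base, sm.find_gaps(base), aligns,
                                           rng_seed=1, alt_assemblies=alts)
        assert summary["n_gaps_filled"] == 0
        assert summary["n_gaps_unfillable"] == 1

    def test_seeded_determinism_and_seed_independence_of_counts(self, small_scenario):
        sc = small_scenario
        aligns = align_to_all(sc["base"], sc["alts"])
        gaps = sm.find_gaps(sc["base"])
        a1, _, s1 = rc.fill_gaps(sc["base"], gaps, aligns, rng_seed=1,
                                 alt_assemblies=sc["alts"])
        a1b, _, s1b = rc.fill_gaps(sc["base"], gaps, aligns, rng_seed=1,
                                   alt_assemblies=sc["alts"])
        a2, _, s2 = rc.fill_gaps(sc["base"], gaps, aligns, rng_seed=2,
                                 alt_assemblies=sc["alts"])
        assert all(a1[s.id].sequence == s.sequence for s in a1b)
        assert s1 == s1b
        assert s1["n_gaps_filled"] == s2["n_gaps_filled"]

    def test_monotonic_gap_and_contig_n50(self, pipeline_run):
        sc, hybrid, _, _ = pipeline_run
        before, after = sm.compute_stats(sc["base"]), sm.compute_stats(hybrid)
        assert after.n_gaps < before.n_gaps
        assert after.gap_total_length < before.gap_total_length
        assert after.contig_n50 >= before.contig_n50


@pytest.fixture(scope="module")
def split_scenario():
    cfg = small_config(seed=13, n_misjoins=0, n_chromosome_splits=1)
    return build_scenario(cfg)


class TestMergeScaffolds:
    def test_split_chromosome_is_remerged(self, split_scenario):
        sc = split_scenario
        params = rc.ReconcileParams(min_merge_len=50_000)
        aligns = align_to_all(sc["base"], sc["alts"], params.align)
        merged, edits = rc.merge_scaffolds(sc["base"], aligns, params)
        assert len(edits) == 1
        split = sc["record"].splits[0]
        assert edits[0].base_id == split["left_id"]
        assert edits[0].donor_id == split["right_id"]
        mrec = sm.compose_truth_record(merged, sc["records"])
        merged_id = f"{split['left_id']}+{split['right_id']}"
        assert mrec.is_collinear(merged_id)

    def test_no_merge_without_spanning_evidence(self, small_scenario):
        sc = small_scenario
        params = rc.ReconcileParams(min_merge_len=50_000)
        aligns = align_to_all(sc["base"], sc["alts"], params.align)
        merged, edits = rc.merge_scaffolds(sc["base"], aligns, params)
        assert edits == []  # scaffolds are whole chromosomes; no adjacency

    def test_single_alternate_evidence_insufficient(self, split_scenario):
        sc = split_scenario
        params = rc.ReconcileParams(min_merge_len=50_000, min_merge_evidence=2)
        one = {"alt1": sc["alts"]["alt1"]}
        aligns = align_to_all(sc["base"], one, params.align)
        merged, edits = rc.merge_scaffolds(sc["base"], aligns, params)
        assert edits == []


class TestPipeline:
    def test_identical_alternates_fixed_point(self):
        seq = _rand_seq(50_000, 20)
        scaf = seq[:25_000] + "N" * 300 + seq[25_000:]
        base = AssemblySet("base", [Scaffold("s", scaf)])
        alts = {f"alt{i}": AssemblySet(f"alt{i}", [Scaffold("s", scaf)]) for i in (1, 2)}
        hybrid, report, _ = sm.reconcile_pipeline(base, alts, seed=0)
        assert hybrid["s"].sequence == scaf
        assert report.n_blocks_replaced == report.n_gaps_filled == report.n_merges == 0

    def test_fewer_than_two_alternates_rejected(self, small_scenario):
        sc = small_scenario
        one = dict(list(sc["alts"].items())[:1])
        with pytest.raises(ValueError, match="2 alternate"):
            sm.reconcile_pipeline(sc["base"], one)

    def test_seeded_determinism(self, pipeline_run):
        sc, hybrid, report, _ = pipeline_run
        h2, r2, _ = sm.reconcile_pipeline(sc["base"], sc["alts"], seed=sc["cfg"].seed)
        assert [s.id for s in hybrid] == [s.id for s in h2]
        assert all(hybrid[s.id].sequence == s.sequence for s in h2)
        assert [e.to_dict() for e in report.edits] == [e.to_dict() for e in r2.edits]

    def test_rerun_converges(self, pipeline_run):
        sc, hybrid, report, _ = pipeline_run
        h2, r2, _ = sm.reconcile_pipeline(hybrid, sc["alts"], seed=sc["cfg"].seed)
        n1 = report.n_blocks_replaced + report.n_gaps_filled
        n2 = r2.n_blocks_replaced + r2.n_gaps_filled
        assert n2 <= n1

    def test_misjoins_eliminated_and_collinear(self, pipeline_run):
        sc, hybrid, _, _ = pipeline_run
        hrec = sm.compose_truth_record(hybrid, sc["records"])
        assert all(hrec.is_collinear(s.id) for s in hybrid)
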