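"""Truth-genome generation, corruption, alternates, BAC pairs, liftover."""

import math

import numpy as np
import pytest

import scaffmend as sm
from scaffmend.simulator import _alternate_cuts, _cut_positions
from scaffmend.validation import classify_pairs
from conftest import small_config


class TestGenerateTruth:
    def test_gc_fraction_within_binomial_bound(self):
        cfg = sm.SimConfig(seed=1, n_chromosomes=1, chromosome_length=100_000,
                           gc_fraction=0.5, repeat_fraction=0.0, bac_n_pairs=0)
        truth = sm.generate_truth(cfg)
        seq = truth["chr1"].sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_determinism(self):
        cfg = small_config(seed=3)
        t1, t2 = sm.generate_truth(cfg), sm.generate_truth(cfg)
        assert all(t1[s.id].sequence == s.sequence for s in t2)

    def test_repeat_fraction_zero_records_no_tracts(self):
        cfg = small_config(seed=3, repeat_fraction=0.0)
        truth = sm.generate_truth(cfg)
        assert all(not v for v in truth.repeat_tracts.values())

    def test_repeat_tracts_cover_requested_fraction(self):
        cfg = small_config(seed=3)
        truth = sm.generate_truth(cfg)
        for s in truth:
            covered = sum(b - a for a, b in truth.repeat_tracts[s.id])
            assert covered >= cfg.repeat_fraction * s.length


class TestCorruptToBase:
    def test_no_events_restores_truth_after_removing_n(self, small_scenario):
        cfg = small_config(seed=4, n_misjoins=0)
        truth = sm.generate_truth(cfg)
        base, record = sm.corrupt_to_base(truth, cfg)
        for s, c in zip(base, truth):
            assert s.sequence.replace("N", "") == c.sequence

    def test_gap_count_equals_junction_count(self, small_scenario):
        sc = small_scenario
        cfg = sc["cfg"]
        expected = cfg.n_chromosomes * (cfg.base_n_fragments - 1)
        assert len(sm.find_gaps(sc["base"])) == expected
        assert len(sc["record"].gaps) == expected

    def test_misjoins_create_cross_chromosome_junctions(self, small_scenario):
        sc = small_scenario
        # each insertion-type misjoin creates two junctions whose flanks lift
        # to different truth chromosomes
        cross = 0
        for sid, segs in sc["record"].segments.items():
            seqs = [s for s in segs if s.kind == "seq"]
            cross += sum(a.chrom != b.chrom for a, b in zip(seqs, seqs[1:]))
        assert cross == 2 * sc["cfg"].n_misjoins

    def test_misjoin_junctions_coincide_with_gaps(self, small_scenario):
        record = small_scenario["record"]
        gapset = {(g["scaffold"], g["start"], g["end"]) for g in record.gaps}
        for mj in record.misjoins:
            for g in mj["junction_gaps"]:
                assert (mj["target_scaffold"], g[0], g[1]) in gapset

    def test_too_many_events_raise(self):
        cfg = small_config(n_misjoins=50)
        truth = sm.generate_truth(cfg)
        with pytest.raises(ValueError):
            sm.corrupt_to_base(truth, cfg)

    def test_liftover_segments_tile_each_scaffold(self, small_scenario):
        sc = small_scenario
        for s in sc["base"]:
            assert sum(seg.length for seg in sc["record"].segments[s.id]) == s.length


class TestMakeAlternates:
    def test_contigs_reconstruct_truth(self, small_scenario):
        sc = small_scenario
        for asm, rec in [(a, sc["records"][a.name]) for a in sc["alts"].values()]:
            rebuilt = {}
            for c in asm:
                seg = rec.segments[c.id][0]
                rebuilt.setdefault(seg.chrom, []).append((seg.t_start, c.sequence))
            for chrom, parts in rebuilt.items():
                joined = "".join(s for _, s in sorted(parts))
                assert joined == sc["truth"][chrom].sequence

    def test_determinism(self):
        cfg = small_config(seed=5)
        truth = sm.generate_truth(cfg)
        a1 = sm.make_alternates(truth, cfg)
        a2 = sm.make_alternates(truth, cfg)
        for (x, _), (y, _) in zip(a1, a2):
            assert all(x[s.id].sequence == s.sequence for s in y)

    def test_junction_spanning_probability(self):
        """Monte-Carlo: with 3 alternates of ~10 fragments per 1 Mb
        chromosome, the average base junction is spanned with 5 kb flanks by
        at least 2 alternates in >= 90% of cases."""
        rng = np.random.default_rng(0)
        L, flank, good, total = 1_000_000, 5_000, 0, 0
        for _ in range(100):
            junctions = _cut_positions(rng, L, 11, 30_000)
            alt_cut_sets = [_cut_positions(rng, L, 10, 1_000) for _ in range(3)]
            for t in junctions:
                spanning = sum(all(abs(c - t) > flank for c in cuts)
                               for cuts in alt_cut_sets)
                good += spanning >= 2
                total += 1
        assert good / total >= 0.9

    def test_event_sites_are_spanned_by_alternates(self, small_scenario):
        sc = small_scenario
        cfg = sc["cfg"]
        cuts = [_alternate_cuts(sc["truth"], cfg, i) for i in range(cfg.n_alternates)]
        for mj in sc["record"].misjoins:
            chrom, fs, fe = mj["intruder"]
            n = sum(all(not (fs - cfg.event_span_margin <= c <= fe + cfg.event_span_margin)
                        for c in cs[chrom]) for cs in cuts)
            assert n >= cfg.min_spanning_alts


class TestBacPairs:
    def test_insert_mean_clt_bound(self):
        cfg = sm.SimConfig(seed=3, bac_n_pairs=1_000)
        truth = sm.generate_truth(cfg)
        placements = sm.sample_bac_pairs(truth, cfg)
        mean = sum(p.insert for p in placements) / len(placements)
        bound = 3 * cfg.bac_insert_sd / math.sqrt(len(placements))
        assert abs(mean - cfg.bac_insert_mean) <= bound

    def test_projected_onto_truth_all_concordant(self, small_scenario):
        sc = small_scenario
        cfg = sc["cfg"]
        placements = sm.sample_bac_pairs(sc["truth"], cfg)
        pairs = sm.project_pairs(placements, sm.truth_self_record(sc["truth"]))
        classes = classify_pairs(pairs, cfg.bac_insert_mean - 4 * cfg.bac_insert_sd,
                                 cfg.bac_insert_mean + 4 * cfg.bac_insert_sd)
        assert all(c.verdict == "concordant" for c in classes)

    def test_pairs_straddling_misjoin_are_discordant_on_base(self, small_scenario):
        sc = small_scenario
        cfg = sc["cfg"]
        placements = sm.sample_bac_pairs(sc["truth"], cfg)
        pairs = sm.project_pairs(placements, sc["record"])
        classes = {c.pair_id: c for c in classify_pairs(
            pairs, cfg.bac_insert_mean - 4 * cfg.bac_insert_sd,
            cfg.bac_insert_mean + 4 * cfg.bac_insert_sd)}
        # every pair whose two ends lift to different scaffolds is discordant
        byid = {p.pair_id: p for p in pairs}
        n = 0
        for pid, c in classes.items():
            p = byid[pid]
            if p.end1.scaffold and p.end2.scaffold and p.end1.scaffold != p.end2.scaffold:
                assert c.verdict == "discordant" and c.reason == "different_scaffold"
                n += 1
        assert n > 0

    def test_determinism(self):
        cfg = small_config(seed=6)
        truth = sm.generate_truth(cfg)
        assert sm.sample_bac_pairs(truth, cfg) == sm.sample_bac_pairs(truth, cfg)


class TestLiftover:
    def test_map_truth_interval_strand_aware(self):
        rec = sm.TruthRecord()
        rec.segments["s"] = [sm.Segment("seq", 100, "chr1", 200, 300, "-")]
        idx = rec.truth_index()
        hit = sm.map_truth_interval(idx, "chr1", 250, 260)
        assert hit == ("s", 40, 50, "-")

    def test_compose_merges_seamless_edits(self, small_scenario):
        sc = small_scenario
        hybrid, report, _ = sm.reconcile_pipeline(sc["base"], sc["alts"],
                                                  seed=sc["cfg"].seed)
        hrec = sm.compose_truth_record(hybrid, sc["records"])
        # a filled gap leaves no liftover boundary: fewer seq segments than
        # the corrupted base had
        n_before = sum(1 for segs in sc["record"].segments.values()
                       for s in segs if s.kind == "seq")
        n_after = sum(1 for segs in hrec.segments.values()
                      for s in segs if s.kind == "seq")
        assert n_after < n_before
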