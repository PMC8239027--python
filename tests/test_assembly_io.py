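"""FASTA I/O, gap location, contig splitting, contiguity statistics, AGP."""

import random

import pytest
from hypothesis import given, settings, strategies as st

import scaffmend as sm
from scaffmend.assembly_io import (
    AssemblySet, Scaffold, SeqComponent, GapComponent,
    nx_curve, render_components,
)


def _write_fasta(tmp_path, text, name="a.fa"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadAssembly:
    def test_basic_parse(self, tmp_path):
        asm = sm.read_assembly(_write_fasta(tmp_path, ">a\nACGT\n>b\nNNAC\n"))
        assert len(asm) == 2
        assert asm["a"].length == 4 and asm["b"].length == 4

    def test_duplicate_id_raises(self, tmp_path):
        with pytest.raises(ValueError, match="'a'"):
            sm.read_assembly(_write_fasta(tmp_path, ">a\nACGT\n>a\nGG\n"))

    def test_case_and_u_normalization(self, tmp_path):
        asm = sm.read_assembly(_write_fasta(tmp_path, ">a\nacgTN\n>b\nAUGU\n"))
        assert asm["a"].sequence == "ACGTN"
        assert asm["b"].sequence == "ATGT"

    def test_empty_file_raises(self, tmp_path):
        with pytest.raises(ValueError):
            sm.read_assembly(_write_fasta(tmp_path, ""))

    def test_iupac_codes_preserved_with_warning(self, tmp_path, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            asm = sm.read_assembly(_write_fasta(tmp_path, ">a\nACRYGT\n"))
        assert asm["a"].sequence == "ACRYGT"
        assert any("ambiguity" in r.message for r in caplog.records)

    def test_round_trip_byte_exact(self, tmp_path):
        random.seed(0)
        seqs = {f"s{i}": "".join(random.choices("ACGTN", k=random.randrange(1, 400)))
                for i in range(5)}
        asm = AssemblySet("x", [Scaffold(k, v) for k, v in seqs.items()])
        out = tmp_path / "out.fa"
        sm.write_assembly(asm, out)
        back = sm.read_assembly(out)
        assert {s.id: s.sequence for s in back} == seqs


class TestFindGaps:
    def test_no_n(self):
        asm = AssemblySet("x", [Scaffold("a", "ACGTACGT")])
        assert sm.find_gaps(asm) == []

    def test_maximal_runs(self):
        asm = AssemblySet("x", [Scaffold("a", "AANNNAAN")])
        gaps = sm.find_gaps(asm)
        assert [(g.start, g.end, g.length) for g in gaps] == [(2, 5, 3), (7, 8, 1)]

    def test_min_gap_len_filter(self):
        asm = AssemblySet("x", [Scaffold("a", "AANNNAAN")])
        assert [(g.start, g.end) for g in sm.find_gaps(asm, 2)] == [(2, 5)]

    def test_invariant_to_scaffold_order(self):
        a, b = Scaffold("a", "ANNA"), Scaffold("b", "NNAANN")
        g1 = sm.find_gaps(AssemblySet("x", [a, b]))
        g2 = sm.find_gaps(AssemblySet("x", [b, a]))
        assert sorted((g.scaffold_id, g.start) for g in g1) == \
            sorted((g.scaffold_id, g.start) for g in g2)


class TestSplitIntoContigs:
    def test_basic_split(self):
        asm = AssemblySet("x", [Scaffold("s", "AANNNAA")])
        contigs = sm.split_into_contigs(asm, 1)
        assert [(c.id, c.sequence) for c in contigs] == [("s.1", "AA"), ("s.2", "AA")]

    def test_gap_below_threshold_not_split(self):
        asm = AssemblySet("x", [Scaffold("s", "AANNNAA")])
        contigs = sm.split_into_contigs(asm, 5)
        assert [c.sequence for c in contigs] == ["AANNNAA"]

    def test_all_n_scaffold_emits_nothing(self, caplog):
        import logging
        asm = AssemblySet("x", [Scaffold("s", "NNNN")])
        with caplog.at_level(logging.WARNING):
            contigs = sm.split_into_contigs(asm, 1)
        assert len(contigs) == 0

    @given(st.lists(st.sampled_from("ACGTN"), min_size=1, max_size=200))
    @settings(max_examples=60, deadline=None)
    def test_length_conservation(self, chars):
        seq = "".join(chars)
        asm = AssemblySet("x", [Scaffold("s", seq)])
        contigs = sm.split_into_contigs(asm, 1)
        gaps = sm.find_gaps(asm, 1)
        assert sum(c.length for c in contigs) + sum(g.length for g in gaps) == len(seq)


def brute_force_nx(lengths, x):
    """Independent NX oracle: walk the sorted prefix sums directly."""
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    cum = 0
    for l in srt:
        cum += l
        if cum * 100 >= x * total:
            return l
    return srt[-1]


class TestComputeStats:
    def test_single_sequence(self):
        asm = AssemblySet("x", [Scaffold("a", "A" * 100)])
        stats = sm.compute_stats(asm)
        assert stats.n50 == 100
        assert all(l == 100 for _, l in stats.nx_curve)

    def test_three_lengths(self):
        asm = AssemblySet("x", [Scaffold("a", "A" * 50), Scaffold("b", "A" * 40),
                                Scaffold("c", "A" * 10)])
        assert sm.compute_stats(asm).n50 == 50

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sm.compute_stats(AssemblySet("x"))

    def test_invariants(self, small_scenario):
        stats = sm.compute_stats(small_scenario["base"])
        curve = dict(stats.nx_curve)
        assert stats.n50 == curve[50]
        vals = [l for _, l in stats.nx_curve]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert stats.contig_n50 <= stats.n50

    def test_nx_against_brute_force(self):
        rng = random.Random(42)
        for _ in range(60):
            lengths = [rng.randrange(1, 10_000) for _ in range(rng.randrange(1, 40))]
            curve = dict(nx_curve(lengths))
            for x in (1, 10, 50, 90, 100):
                assert curve[x] == brute_force_nx(lengths, x), (lengths, x)


class TestAgp:
    def test_unedited_scaffold_single_w_row(self, tmp_path):
        asm = AssemblySet("base", [Scaffold("s", "ACGT" * 25)])
        out = tmp_path / "x.agp"
        sm.write_agp(asm, out)
        rows = [l.split("\t") for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(rows) == 1
        assert rows[0][:9] == ["s", "1", "100", "1", "W", "base:s", "1", "100", "+"]

    def test_gap_fill_three_rows(self, tmp_path):
        asm = AssemblySet("base")
        asm.add(Scaffold("s", "A" * 30), [
            SeqComponent("base", "s", 0, 10, "+"),
            SeqComponent("alt1", "c1", 5, 15, "+"),
            SeqComponent("base", "s", 20, 30, "+"),
        ])
        out = tmp_path / "x.agp"
        sm.write_agp(asm, out)
        rows = [l.split("\t") for l in out.read_text().splitlines() if not l.startswith("#")]
        assert [r[4] for r in rows] == ["W", "W", "W"]
        assert rows[1][5] == "alt1:c1" and rows[1][6:9] == ["6", "15", "+"]

    def test_merge_w_n_w(self, tmp_path):
        asm = AssemblySet("base")
        asm.add(Scaffold("m", "A" * 10 + "N" * 100 + "C" * 10), [
            SeqComponent("base", "a", 0, 10, "+"),
            GapComponent(100),
            SeqComponent("base", "b", 0, 10, "-"),
        ])
        out = tmp_path / "x.agp"
        sm.write_agp(asm, out)
        rows = [l.split("\t") for l in out.read_text().splitlines() if not l.startswith("#")]
        assert [r[4] for r in rows] == ["W", "N", "W"]
        assert rows[1][5:9] == ["100", "scaffold", "yes", "align_genus"]
        assert rows[2][8] == "-"

    def test_inconsistent_provenance_raises(self, tmp_path):
        asm = AssemblySet("base")
        asm.add(Scaffold("s", "ACGT"), [SeqComponent("base", "s", 0, 3, "+")])
        with pytest.raises(ValueError, match="span"):
            sm.write_agp(asm, tmp_path / "x.agp")


def test_render_components_reverse_strand():
    src = AssemblySet("alt", [Scaffold("c", "AACCGGTT")])
    comps = [SeqComponent("alt", "c", 2, 6, "-"), GapComponent(2)]
    assert render_components(comps, {"alt": src}) == "CCGGNN"
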