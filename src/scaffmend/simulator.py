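"""Synthetic truth genomes with machine-readable provenance.

The generator emulates the study design behind consensus reconciliation:
one *base* assembly whose scaffolds were produced by cutting each truth
chromosome into fragments and re-joining them across N-gaps — except at
injected misjoins, where a fragment from a different chromosome is spliced
in (and removed from its source), and at injected inversions, where a
fragment is strand-flipped in place; plus two or more *alternate*
assemblies, each an independent gap-free fragmentation of the same truth.
BAC-end pairs are drawn from the truth with a normal insert-size
distribution and can be projected exactly onto any assembly through the
recorded liftover segments, so no aligner is needed to validate claims.

Every output is a pure function of :class:`SimConfig` (seed included).
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict

import numpy as np

from .assembly_io import (
    AssemblySet, Scaffold, GapComponent, SeqComponent, Component,
    reverse_complement,
)
from .validation import End, PairAlignment


@dataclass
class SimConfig:
    """Scenario parameters; the defaults define the standard study scenario
    (three 1 Mb chromosomes, three alternates, five misjoins, 30 gaps)."""

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 1_000_000
    gc_fraction: float = 0.41
    repeat_fraction: float = 0.05
    repeat_unit_length: int = 150
    base_n_fragments: int = 11          # per chromosome -> 10 junction gaps
    base_gap_length: tuple[int, int] = (100, 2_000)
    n_misjoins: int = 5
    n_inversions: int = 0
    inversion_length: tuple[int, int] = (30_000, 120_000)
    n_alternates: int = 3
    alt_n_fragments: int = 4            # per chromosome (alternates are more
                                        # contiguous than the base — the
                                        # premise of consensus reconciliation)
    bac_n_pairs: int = 1_000
    bac_insert_mean: int = 150_000
    bac_insert_sd: int = 20_000
    bac_read_length: int = 150
    min_fragment_len: int = 30_000
    n_chromosome_splits: int = 0        # split chromosomes into 2 base scaffolds
    alt_misjoin_rate: float = 0.0       # chance of one chimeric contig per alternate
    error_rate: float = 0.0             # per-base substitutions in alternates
    event_span_margin: int = 15_000     # flank an alternate must cover around
                                        # an injected event to count as
                                        # contiguous across it
    min_spanning_alts: int = 2          # events are placed only where this many
                                        # alternates are contiguous across them

    def validate(self) -> None:
        assert self.n_chromosomes >= 1 and self.chromosome_length > 0
        assert 0.0 <= self.gc_fraction <= 1.0
        assert 0.0 <= self.repeat_fraction <= 1.0
        assert self.base_gap_length[0] <= self.base_gap_length[1]
        assert self.inversion_length[0] <= self.inversion_length[1]
        assert min(self.n_misjoins, self.n_inversions, self.bac_n_pairs) >= 0
        if self.n_misjoins > 0:
            assert self.base_n_fragments >= 2
        if self.bac_n_pairs > 0:
            assert self.bac_insert_mean + 4 * self.bac_insert_sd < self.chromosome_length


# ---------------------------------------------------------------------------
# Truth record / liftover
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One liftover segment of an assembly sequence: either ``kind='seq'``
    (maps to truth ``chrom[t_start:t_end]``, reverse-complemented when
    strand is '-') or ``kind='gap'`` (a run of N)."""

    kind: str
    length: int
    chrom: str = ""
    t_start: int = 0
    t_end: int = 0
    strand: str = "+"


@dataclass
class TruthRecord:
    """Liftover segments tiling each sequence of an assembly, plus the
    injected-event log for a corrupted base assembly."""

    segments: dict[str, list[Segment]] = field(default_factory=dict)
    misjoins: list[dict] = field(default_factory=list)
    inversions: list[dict] = field(default_factory=list)
    gaps: list[dict] = field(default_factory=list)
    splits: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        d = {"segments": {k: [asdict(s) for s in v] for k, v in self.segments.items()},
             "misjoins": self.misjoins, "inversions": self.inversions,
             "gaps": self.gaps, "splits": self.splits}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    def write_bed(self, path) -> None:
        """Liftover segments as BED on the assembly (truth coords in name)."""
        with open(path, "w") as fh:
            for sid, segs in self.segments.items():
                pos = 0
                for s in segs:
                    if s.kind == "seq":
                        fh.write(f"{sid}\t{pos}\t{pos + s.length}\t"
                                 f"{s.chrom}:{s.t_start}-{s.t_end}\t0\t{s.strand}\n")
                    pos += s.length

    # -- liftover -----------------------------------------------------------
    def truth_index(self):
        """Per-chromosome sorted (t_start, t_end, scaffold, scaf_pos, strand)."""
        idx: dict[str, list[tuple[int, int, str, int, str]]] = {}
        for sid, segs in self.segments.items():
            pos = 0
            for s in segs:
                if s.kind == "seq":
                    idx.setdefault(s.chrom, []).append((s.t_start, s.t_end, sid, pos, s.strand))
                pos += s.length
        for lst in idx.values():
            lst.sort()
        return idx

    def is_collinear(self, scaffold_id: str) -> bool:
        """True iff the scaffold's seq segments lie on one chromosome, one
        strand, in monotonically advancing truth order."""
        segs = [s for s in self.segments[scaffold_id] if s.kind == "seq"]
        if not segs:
            return True
        if len({s.chrom for s in segs}) > 1 or len({s.strand for s in segs}) > 1:
            return False
        coords = [(s.t_start, s.t_end) for s in segs]
        if segs[0].strand == "-":
            coords = coords[::-1]
        return all(a[1] <= b[0] for a, b in zip(coords, coords[1:]))


def map_truth_interval(index, chrom: str, start: int, end: int):
    """Project truth interval [start, end) onto the assembly behind
    ``index`` (from :meth:`TruthRecord.truth_index`).

    Returns (scaffold, start, end, strand) or None if the interval is not
    fully contained in a single liftover segment."""
    segs = index.get(chrom)
    if not segs:
        return None
    i = bisect_right(segs, (start, float("inf"))) - 1
    for j in (i, i - 1):  # guard against zero-length/nested edge cases
        if 0 <= j < len(segs):
            t0, t1, sid, pos, strand = segs[j]
            if t0 <= start and end <= t1:
                if strand == "+":
                    return sid, pos + (start - t0), pos + (end - t0), "+"
                return sid, pos + (t1 - end), pos + (t1 - start), "-"
    return None


def _merge_segments(segs: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for s in segs:
        if s.length == 0:
            continue
        if out and s.kind == "seq" and out[-1].kind == "seq" \
                and out[-1].chrom == s.chrom and out[-1].strand == s.strand:
            p = out[-1]
            if s.strand == "+" and p.t_end == s.t_start:
                out[-1] = Segment("seq", p.length + s.length, s.chrom, p.t_start, s.t_end, "+")
                continue
            if s.strand == "-" and p.t_start == s.t_end:
                out[-1] = Segment("seq", p.length + s.length, s.chrom, s.t_start, p.t_end, "-")
                continue
        if out and s.kind == "gap" and out[-1].kind == "gap":
            out[-1] = Segment("gap", out[-1].length + s.length)
            continue
        out.append(s)
    return out


def _slice_segments(segs: list[Segment], start: int, end: int) -> list[Segment]:
    out: list[Segment] = []
    pos = 0
    for s in segs:
        lo, hi = max(pos, start), min(pos + s.length, end)
        if lo < hi:
            if s.kind == "gap":
                out.append(Segment("gap", hi - lo))
            elif s.strand == "+":
                out.append(Segment("seq", hi - lo, s.chrom,
                                   s.t_start + (lo - pos), s.t_start + (hi - pos), "+"))
            else:
                out.append(Segment("seq", hi - lo, s.chrom,
                                   s.t_end - (hi - pos), s.t_end - (lo - pos), "-"))
        pos += s.length
    return out


def _flip_segment(s: Segment) -> Segment:
    if s.kind == "gap":
        return s
    return Segment("seq", s.length, s.chrom, s.t_start, s.t_end,
                   "-" if s.strand == "+" else "+")


def compose_truth_record(asm: AssemblySet,
                         records: dict[str, TruthRecord]) -> TruthRecord:
    """Truth record of an edited assembly, composed through its provenance
    components and the truth records of the source assemblies.

    Adjacent truth-contiguous segments are merged, so a seamless edit
    leaves no liftover boundary."""
    out = TruthRecord()
    for s in asm:
        segs: list[Segment] = []
        for c in asm.provenance[s.id]:
            if isinstance(c, GapComponent):
                segs.append(Segment("gap", c.length))
                continue
            src = records[c.assembly].segments[c.seq_id]
            piece = _slice_segments(src, c.start, c.end)
            if c.strand == "-":
                piece = [_flip_segment(x) for x in reversed(piece)]
            segs.extend(piece)
        out.segments[s.id] = _merge_segments(segs)
    return out


# ---------------------------------------------------------------------------
# Truth genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_truth(config: SimConfig) -> AssemblySet:
    """I.i.d. bases at the configured GC fraction with interspersed exact
    tandem repeat tracts covering ``repeat_fraction`` of each chromosome."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    truth = AssemblySet("truth")
    tracts: dict[str, list[tuple[int, int]]] = {}
    for i in range(config.n_chromosomes):
        L = config.chromosome_length
        arr = rng.choice(_BASES, size=L, p=p)
        target = int(config.repeat_fraction * L)
        placed = 0
        cid = f"chr{i + 1}"
        tracts[cid] = []
        while placed < target:
            unit = rng.choice(_BASES, size=config.repeat_unit_length, p=p)
            copies = int(rng.integers(8, 17))
            tract = np.tile(unit, copies)[: max(1, min(L, 16 * config.repeat_unit_length))]
            pos = int(rng.integers(0, L - len(tract)))
            arr[pos:pos + len(tract)] = tract
            tracts[cid].append((pos, pos + len(tract)))
            placed += len(tract)
        truth.add(Scaffold(cid, arr.tobytes().decode("ascii")))
    truth.repeat_tracts = tracts  # type: ignore[attr-defined]
    return truth


def truth_self_record(truth: AssemblySet) -> TruthRecord:
    """The identity liftover of the truth genome onto itself."""
    rec = TruthRecord()
    for s in truth:
        rec.segments[s.id] = [Segment("seq", s.length, s.id, 0, s.length, "+")]
    return rec


# ---------------------------------------------------------------------------
# Base assembly corruption
# ---------------------------------------------------------------------------

@dataclass
class _Frag:
    uid: int
    chrom: str
    start: int
    end: int
    strand: str = "+"
    has_event: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


_TRACT_MARGIN = 2_000  # cuts keep this distance from tandem-repeat tracts,
                       # where anchor positions are ambiguous by one unit


def _cut_positions(rng, L: int, n_fragments: int, min_len: int,
                   forbidden: list[tuple[int, int]] = ()) -> list[int]:
    if n_fragments <= 1:
        return []
    for _ in range(10_000):
        cuts = np.sort(rng.integers(min_len, L - min_len + 1, size=n_fragments - 1))
        bounds = np.concatenate([[0], cuts, [L]])
        if not np.all(np.diff(bounds) >= min_len):
            continue
        if any(a - _TRACT_MARGIN <= c <= b + _TRACT_MARGIN
               for c in cuts.tolist() for a, b in forbidden):
            continue
        return cuts.tolist()
    raise ValueError("cannot place fragment cuts with the requested spacing; "
                     "reduce n_fragments or min_fragment_len")


def _alternate_cuts(truth: AssemblySet, config: SimConfig, ai: int
                    ) -> dict[str, list[int]]:
    """Cut positions of alternate ``ai`` (pure function of config.seed, so
    the corruption step can honour the contiguity preconditions without
    building the alternates)."""
    rng = np.random.default_rng([config.seed, 2, ai])
    tracts = getattr(truth, "repeat_tracts", {})
    return {s.id: _cut_positions(rng, s.length, config.alt_n_fragments, 1_000,
                                 tracts.get(s.id, []))
            for s in truth}


def _n_spanning_alts(all_cuts: list[dict[str, list[int]]], chrom: str,
                     lo: int, hi: int) -> int:
    """How many alternates have a contig contiguous across [lo, hi]."""
    return sum(all(not (lo <= c <= hi) for c in cuts[chrom]) for cuts in all_cuts)


def corrupt_to_base(truth: AssemblySet, config: SimConfig
                    ) -> tuple[AssemblySet, TruthRecord]:
    """Fragment each chromosome and re-join across N-gaps, injecting
    ``n_misjoins`` interchromosomal insertions (a fragment moved between
    two truly adjacent fragments of another chromosome) and
    ``n_inversions`` strand-flipped fragments.  Misjoin junctions always
    coincide with gaps.  Every event is logged in the TruthRecord."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    frags: dict[str, list[_Frag]] = {}
    uid = 0
    tracts = getattr(truth, "repeat_tracts", {})
    for s in truth:
        cuts = _cut_positions(rng, s.length, config.base_n_fragments,
                              config.min_fragment_len, tracts.get(s.id, []))
        bounds = [0] + cuts + [s.length]
        frags[s.id] = []
        for a, b in zip(bounds, bounds[1:]):
            frags[s.id].append(_Frag(uid, s.id, a, b))
            uid += 1
    total_junctions = sum(len(v) - 1 for v in frags.values())
    if config.n_misjoins + config.n_inversions > total_junctions:
        raise ValueError("more events requested than junctions available")

    alt_cuts = [_alternate_cuts(truth, config, ai)
                for ai in range(config.n_alternates)]
    margin = config.event_span_margin

    def _spanned(chrom: str, lo: int, hi: int) -> bool:
        return _n_spanning_alts(alt_cuts, chrom, lo - margin, hi + margin) \
            >= config.min_spanning_alts

    events: list[dict] = []
    chrom_ids = list(frags)
    for _ in range(config.n_misjoins):
        placed = False
        for _try in range(10_000):
            src = chrom_ids[int(rng.integers(len(chrom_ids)))]
            if len(frags[src]) < 3:
                continue
            si = int(rng.integers(1, len(frags[src]) - 1))
            f = frags[src][si]
            if f.has_event or frags[src][si - 1].has_event or frags[src][si + 1].has_event:
                continue
            # the method can only re-insert the moved fragment if an
            # alternate contig is contiguous across its whole truth span
            if not _spanned(f.chrom, f.start, f.end):
                continue
            tgt = chrom_ids[int(rng.integers(len(chrom_ids)))]
            if tgt == src or len(frags[tgt]) < 2:
                continue
            tj = int(rng.integers(1, len(frags[tgt])))
            if frags[tgt][tj - 1].has_event or frags[tgt][tj].has_event:
                continue
            tpos = frags[tgt][tj].start  # the true junction receiving the intruder
            if not _spanned(tgt, tpos, tpos):
                continue
            # move fragment f between tgt[tj-1] and tgt[tj]
            frags[src].pop(si)
            frags[tgt].insert(tj, f)
            # the two source-side neighbours now flank a deletion-type
            # junction; a second removal next to it would widen the missing
            # span beyond what any alternate contig can re-insert
            f.has_event = True
            frags[src][si - 1].has_event = True
            frags[src][si].has_event = True
            events.append({"kind": "misjoin", "intruder_uid": f.uid,
                           "source_chrom": src, "target_chrom": tgt,
                           "intruder": [f.chrom, f.start, f.end],
                           "source_left_uid": frags[src][si - 1].uid,
                           "source_right_uid": frags[src][si].uid})
            placed = True
            break
        if not placed:
            raise ValueError("could not place all requested misjoins")

    for _ in range(config.n_inversions):
        lo, hi = config.inversion_length
        cands = [(cid, i) for cid in chrom_ids
                 for i in range(1, len(frags[cid]) - 1)
                 if not frags[cid][i].has_event
                 and not frags[cid][i - 1].has_event and not frags[cid][i + 1].has_event
                 and _spanned(cid, frags[cid][i].start, frags[cid][i].end)]
        preferred = [c for c in cands if lo <= frags[c[0]][c[1]].length <= hi]
        pool = preferred or cands
        if not pool:
            raise ValueError("could not place all requested inversions")
        cid, i = pool[int(rng.integers(len(pool)))]
        f = frags[cid][i]
        f.strand = "-"
        f.has_event = True
        events.append({"kind": "inversion", "uid": f.uid, "chrom": cid,
                       "interval": [f.start, f.end]})

    # optional chromosome splits (for merge testing)
    scaffold_frag_lists: list[tuple[str, list[_Frag]]] = []
    record = TruthRecord()
    split_chroms = set()
    if config.n_chromosome_splits:
        order = rng.permutation(len(chrom_ids))
        split_chroms = {chrom_ids[int(i)] for i in order[: config.n_chromosome_splits]}
    for ci, cid in enumerate(chrom_ids, 1):
        lst = frags[cid]
        if cid in split_chroms and len(lst) >= 2:
            good = [j for j in range(1, len(lst))
                    if _spanned(cid, lst[j].start, lst[j].start)]
            cut = good[int(rng.integers(len(good)))] if good else int(rng.integers(1, len(lst)))
            scaffold_frag_lists.append((f"scaffold_{ci}a", lst[:cut]))
            scaffold_frag_lists.append((f"scaffold_{ci}b", lst[cut:]))
            record.splits.append({"left_id": f"scaffold_{ci}a", "right_id": f"scaffold_{ci}b",
                                  "chrom": cid})
        else:
            scaffold_frag_lists.append((f"scaffold_{ci}", lst))

    base = AssemblySet("base")
    uid_gap_after: dict[int, tuple[str, int, int]] = {}  # gap following fragment uid
    uid_location: dict[int, str] = {}
    for sid, lst in scaffold_frag_lists:
        parts: list[str] = []
        segs: list[Segment] = []
        pos = 0
        for j, f in enumerate(lst):
            seq = truth[f.chrom].sequence[f.start:f.end]
            if f.strand == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            segs.append(Segment("seq", f.length, f.chrom, f.start, f.end, f.strand))
            uid_location[f.uid] = sid
            pos += f.length
            if j < len(lst) - 1:
                glen = int(rng.integers(config.base_gap_length[0],
                                        config.base_gap_length[1] + 1))
                parts.append("N" * glen)
                segs.append(Segment("gap", glen))
                uid_gap_after[f.uid] = (sid, pos, pos + glen)
                record.gaps.append({"scaffold": sid, "start": pos, "end": pos + glen})
                pos += glen
        base.add(Scaffold(sid, "".join(parts)))
        record.segments[sid] = segs

    frag_lists = dict(scaffold_frag_lists)
    for ev in events:
        ev = dict(ev)
        if ev["kind"] == "misjoin":
            sid = uid_location[ev["intruder_uid"]]
            tgt_list = frag_lists[sid]
            idx = next(i for i, f in enumerate(tgt_list) if f.uid == ev["intruder_uid"])
            left_gap = uid_gap_after.get(tgt_list[idx - 1].uid)
            right_gap = uid_gap_after.get(ev["intruder_uid"])
            src_gap = uid_gap_after.get(ev["source_left_uid"])
            ev["target_scaffold"] = sid
            ev["junction_gaps"] = [list(g[1:]) if g else None
                                   for g in (left_gap, right_gap)]
            ev["source_scaffold"] = uid_location[ev["source_left_uid"]]
            ev["source_gap"] = list(src_gap[1:]) if src_gap else None
            record.misjoins.append(ev)
        else:
            ev["scaffold"] = uid_location[ev["uid"]]
            record.inversions.append(ev)
    return base, record


# ---------------------------------------------------------------------------
# Alternate assemblies
# ---------------------------------------------------------------------------

def make_alternates(truth: AssemblySet, config: SimConfig
                    ) -> list[tuple[AssemblySet, TruthRecord]]:
    """Independent gap-free fragmentations of the truth, one per alternate.

    Cut positions are independent across alternates, so most base junctions
    are spanned with generous flanks by at least two alternates.  An
    optional per-base error rate and chimeric-contig rate stress the
    anchor matching and the consensus check."""
    config.validate()
    if config.n_alternates < 2:
        raise ValueError("n_alternates must be >= 2")
    out: list[tuple[AssemblySet, TruthRecord]] = []
    for ai in range(config.n_alternates):
        all_cuts = _alternate_cuts(truth, config, ai)
        rng = np.random.default_rng([config.seed, 4, ai])
        name = f"alt{ai + 1}"
        asm = AssemblySet(name)
        rec = TruthRecord()
        n = 0
        for s in truth:
            bounds = [0] + all_cuts[s.id] + [s.length]
            for a, b in zip(bounds, bounds[1:]):
                n += 1
                cid = f"{name}_c{n:04d}"
                seq = s.sequence[a:b]
                if config.error_rate > 0:
                    seq = _mutate(seq, config.error_rate, rng)
                asm.add(Scaffold(cid, seq))
                rec.segments[cid] = [Segment("seq", b - a, s.id, a, b, "+")]
        if config.alt_misjoin_rate > 0 and rng.random() < config.alt_misjoin_rate:
            ids = asm.ids
            i, j = rng.choice(len(ids), size=2, replace=False)
            a, b = asm[ids[int(i)]], asm[ids[int(j)]]
            n += 1
            cid = f"{name}_chimera{n:04d}"
            chim_segs = rec.segments[a.id] + rec.segments[b.id]
            asm.remove(a.id)
            asm.remove(b.id)
            asm.add(Scaffold(cid, a.sequence + b.sequence))
            del rec.segments[a.id], rec.segments[b.id]
            rec.segments[cid] = chim_segs
        out.append((asm, rec))
    return out


def _mutate(seq: str, rate: float, rng) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits):
        arr[hits] = _BASES[rng.integers(0, 4, size=len(hits))]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# BAC-end pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BacPlacement:
    """Truth placement of one BAC-end pair (inward FR orientation)."""

    pair_id: str
    chrom: str
    start: int       # leftmost base of end1
    insert: int      # outer insert size
    read_length: int

    @property
    def end1(self) -> tuple[int, int, str]:
        return self.start, self.start + self.read_length, "+"

    @property
    def end2(self) -> tuple[int, int, str]:
        return (self.start + self.insert - self.read_length,
                self.start + self.insert, "-")


def sample_bac_pairs(truth: AssemblySet, config: SimConfig) -> list[BacPlacement]:
    """Draw pairs from the truth: chromosome chosen proportional to length,
    insert ~ Normal(mean, sd) truncated to mean +/- 4 sd (and positive),
    inward FR ends.  The truncation makes the sampling support coincide
    with the mean +/- 4 sd classification window, so a discordant verdict
    on simulated data is always structural, never a sampling outlier."""
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    ids = truth.ids
    lens = np.array([truth[c].length for c in ids], dtype=float)
    probs = lens / lens.sum()
    out: list[BacPlacement] = []
    rl = config.bac_read_length
    for i in range(config.bac_n_pairs):
        ci = int(rng.choice(len(ids), p=probs))
        L = int(lens[ci])
        while True:
            ins = int(round(rng.normal(config.bac_insert_mean, config.bac_insert_sd)))
            if 2 * rl < ins <= L and abs(ins - config.bac_insert_mean) <= 4 * config.bac_insert_sd:
                break
        start = int(rng.integers(0, L - ins + 1))
        out.append(BacPlacement(f"bac{i:05d}", ids[ci], start, ins, rl))
    return out


def project_pairs(placements: list[BacPlacement],
                  record: TruthRecord, mapq: int = 60) -> list[PairAlignment]:
    """Project truth placements exactly onto the assembly described by
    ``record`` (no alignment): an end not fully contained in one liftover
    segment is reported unmapped."""
    index = record.truth_index()
    pairs: list[PairAlignment] = []
    for p in placements:
        ends: list[End] = []
        for (a, b, strand) in (p.end1, p.end2):
            hit = map_truth_interval(index, p.chrom, a, b)
            if hit is None:
                ends.append(End(None, -1, ".", 0, p.read_length))
            else:
                sid, s0, _, seg_strand = hit
                out_strand = strand if seg_strand == "+" else ("-" if strand == "+" else "+")
                ends.append(End(sid, s0, out_strand, mapq, p.read_length))
        pairs.append(PairAlignment(p.pair_id, ends[0], ends[1]))
    return pairs
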