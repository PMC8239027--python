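"""Consensus-driven assembly reconciliation.

The base assembly (typically a long-read assembly scaffolded with Hi-C)
is checked against two or more *alternate* de novo assemblies of the same
genome.  Where the alternates disagree with the base but agree with each
other — and the disputed junction sits at an N-gap, the signature of a
scaffolding join — the base region between the nearest shared anchors is
replaced by the corresponding interval of one (randomly chosen) agreeing
alternate, yielding a hybrid assembly.  The same block machinery then fills
N-gaps from gap-free alternate intervals, and finally scaffolds whose ends
are bridged by single alternate contigs can be merged into
pseudo-chromosomes.

Every modification is an :class:`EditRecord` with full coordinate
provenance, and the edited assembly carries an AGP-ready component list.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field, asdict

from intervaltree import IntervalTree

from .assembly_io import (
    AssemblySet, GapTract, GapComponent, SeqComponent, Component, Scaffold,
    find_gaps, reverse_complement,
)
from .alignment import AlignmentBlock, AlignParams, align_assemblies

log = logging.getLogger(__name__)


@dataclass
class ReconcileParams:
    """Tunable thresholds of the reconciliation method (bp unless noted)."""

    merge_window: int = 20_000      # cluster radius for junction candidates
    gap_window: int = 20_000        # check A: max gap distance from a junction
    junction_flank: int = 1_000     # span needed to call an alternate consistent
    jump_tol: int = 10_000          # collinear donor-coordinate jump tolerance
    end_slack: int = 500            # unaligned contig-terminus tolerance
    min_agreeing: int = 2           # check B: agreeing discrepant alternates
    max_replace_span: int = 500_000  # donor continuation search range
    flank: int = 5_000              # aligned flank required around a fillable gap
    max_anchor_dist: int = 2_000    # max anchor distance from a gap edge
    min_event_anchor: int = 50      # min anchor run length trusted for cut points
    min_merge_len: int = 10_000_000
    min_merge_evidence: int = 2
    terminal_window: int = 50_000
    join_gap_len: int = 100
    align: AlignParams = field(default_factory=AlignParams)


@dataclass
class JunctionCandidate:
    """One alternate's discrepancy between two adjacent alignment blocks."""

    base_id: str
    pos: int
    alt_name: str
    category: str  # different_contig | orientation | order | indel_jump
    left: AlignmentBlock
    right: AlignmentBlock


@dataclass
class BreakpointCall:
    """A clustered candidate misjoin on the base assembly."""

    base_id: str
    position: int
    gap_nearby: bool
    evidence: dict[str, str]  # alt name -> consistent_with_base|discrepant|no_coverage
    n_discrepant_agreeing: int
    agreeing_alts: list[str] = field(default_factory=list)
    category: str = ""
    candidates: dict[str, JunctionCandidate] = field(default_factory=dict, repr=False)

    @property
    def actionable(self) -> bool:
        return self.gap_nearby and self.n_discrepant_agreeing >= 2


@dataclass
class EditRecord:
    """One applied modification, in pre-edit coordinates of its stage."""

    kind: str  # block_replacement | gap_fill | merge
    base_id: str
    base_start: int
    base_end: int
    donor_assembly: str
    donor_id: str
    donor_start: int
    donor_end: int
    donor_strand: str
    inserted_length: int
    rng_draw: int = -1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReconcileReport:
    n_breakpoints_called: int = 0
    n_actionable: int = 0
    n_blocks_replaced: int = 0
    n_calls_skipped: int = 0
    n_gaps_filled: int = 0
    filled_gap_total_length: int = 0
    n_gaps_unfillable: int = 0
    n_merges: int = 0
    edits: list[EditRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["edits"] = [e.to_dict() for e in self.edits]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Anchor/coordinate helpers
# ---------------------------------------------------------------------------

def _last_anchor(block: AlignmentBlock, min_len: int = 0):
    """(base_pos, alt_pos_fwd, length) of the block's last trusted anchor
    (length >= ``min_len``; isolated seed-size matches can be chance
    collisions and are not safe cut points).  PAF blocks anchor at their
    endpoints (length 0)."""
    if block.anchors:
        for a in reversed(block.anchors):
            if a.k >= min_len:
                return a.base_pos, a.alt_pos, a.k
        return None
    return (block.base_end,
            block.alt_end if block.strand == "+" else block.alt_start, 0)


def _first_anchor(block: AlignmentBlock, min_len: int = 0):
    if block.anchors:
        for a in block.anchors:
            if a.k >= min_len:
                return a.base_pos, a.alt_pos, a.k
        return None
    return (block.base_start,
            block.alt_start if block.strand == "+" else block.alt_end, 0)


def _first_anchor_after(block: AlignmentBlock, pos: int, min_len: int = 0):
    """First trusted anchor of ``block`` starting strictly after ``pos``."""
    if block.anchors:
        for a in block.anchors:
            if a.base_pos > pos and a.k >= min_len:
                return a.base_pos, a.alt_pos, a.k
        return None
    if block.base_start > pos:
        return _first_anchor(block)
    return None


def _inner_edge(u: tuple[int, int, int], strand: str) -> tuple[int, int, int]:
    """Collapse an upstream anchor run to its inner (right) edge, so the
    replaced interval starts right at the junction rather than at the start
    of a possibly very long exact run."""
    bu, au, lu = u
    return (bu + lu, au + lu if strand == "+" else au, 0)


def _donor_interval(strand: str, u: tuple[int, int, int],
                    v: tuple[int, int, int]) -> tuple[int, int]:
    """Donor forward-strand interval replacing base [u.base_pos, v.base_pos).

    At an anchor the base and donor sequences agree exactly, so cutting at
    anchor starts splices without chimeric joins.
    """
    (_, au, lu), (_, av, lv) = u, v
    if strand == "+":
        return au, av
    return av + lv, au + lu


def _anchors_flanking_gap(block: AlignmentBlock, gap: GapTract, min_len: int = 0):
    """Innermost trusted anchors of ``block`` left/right of the gap."""
    if not block.anchors:
        u = _first_anchor(block)
        v = _last_anchor(block)
        return (u if u[0] + u[2] <= gap.start else None,
                v if v[0] >= gap.end else None)
    u = v = None
    for a in block.anchors:
        if a.k < min_len:
            continue
        if a.base_pos + a.k <= gap.start:
            u = (a.base_pos, a.alt_pos, a.k)
        if v is None and a.base_pos >= gap.end:
            v = (a.base_pos, a.alt_pos, a.k)
    return u, v


# ---------------------------------------------------------------------------
# Provenance-aware splicing
# ---------------------------------------------------------------------------

def _split_components(comps: list[Component], pos: int
                      ) -> tuple[list[Component], list[Component]]:
    left: list[Component] = []
    right: list[Component] = []
    acc = 0
    for c in comps:
        if acc + c.length <= pos:
            left.append(c)
        elif acc >= pos:
            right.append(c)
        else:
            a, b = c.cut(pos - acc)
            if a.length:
                left.append(a)
            if b.length:
                right.append(b)
        acc += c.length
    return left, right


def _splice(asm: AssemblySet, scaf_id: str, start: int, end: int,
            replacement: str, components: list[Component]) -> None:
    """Replace ``[start, end)`` of a scaffold with ``replacement`` (sequence
    and provenance updated together)."""
    s = asm[scaf_id]
    left, rest = _split_components(asm.provenance[scaf_id], start)
    _, right = _split_components(rest, end - start)
    asm.provenance[scaf_id] = left + [c for c in components if c.length] + right
    s.sequence = s.sequence[:start] + replacement + s.sequence[end:]


# ---------------------------------------------------------------------------
# Breakpoint calling
# ---------------------------------------------------------------------------

def _blocks_by_scaffold(blocks: list[AlignmentBlock]) -> dict[str, list[AlignmentBlock]]:
    out: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        out.setdefault(b.base_id, []).append(b)
    for lst in out.values():
        lst.sort(key=lambda b: (b.base_start, b.base_end))
    return out


def _junction_candidates(alt_name: str, blocks: dict[str, list[AlignmentBlock]],
                         params: ReconcileParams) -> list[JunctionCandidate]:
    cands: list[JunctionCandidate] = []
    for base_id, lst in blocks.items():
        for b1, b2 in zip(lst, lst[1:]):
            # judge the junction from trusted anchors: chain-edge anchors can
            # be isolated chance matches that distort the block bounds
            la = _last_anchor(b1, params.min_event_anchor)
            fa = _first_anchor(b2, params.min_event_anchor)
            if la is None or fa is None:
                continue
            left_end = la[0] + la[2]
            right_start = fa[0]
            pos = (left_end + right_start) // 2
            base_jump = right_start - left_end
            if b1.alt_id != b2.alt_id:
                # A junction where the left contig simply ends and the right
                # contig simply starts asserts nothing about adjacency (it is
                # an ordinary contig break); only a contig whose continuation
                # maps elsewhere contradicts the base.
                if b1.strand == "+":
                    left_continues = b1.alt_len - b1.alt_end > params.end_slack
                else:
                    left_continues = b1.alt_start > params.end_slack
                if b2.strand == "+":
                    right_continues = b2.alt_start > params.end_slack
                else:
                    right_continues = b2.alt_len - b2.alt_end > params.end_slack
                if not (left_continues or right_continues):
                    continue
                cat = "different_contig"
            elif b1.strand != b2.strand:
                cat = "orientation"
            else:
                if b1.strand == "+":
                    donor_jump = fa[1] - (la[1] + la[2])
                else:
                    donor_jump = la[1] - (fa[1] + fa[2])
                if donor_jump < -params.jump_tol:
                    cat = "order"
                elif abs(donor_jump - base_jump) > params.jump_tol:
                    cat = "indel_jump"
                else:
                    continue  # consistent junction
            cands.append(JunctionCandidate(base_id, pos, alt_name, cat, b1, b2))
    return cands


def call_breakpoints(base: AssemblySet, gaps: list[GapTract],
                     alignments: dict[str, list[AlignmentBlock]],
                     params: ReconcileParams | None = None) -> list[BreakpointCall]:
    """Emit clustered misjoin candidates with per-alternate verdicts.

    A junction between adjacent blocks of one alternate is a candidate when
    the blocks map to different alternate contigs, to the same contig in
    flipped orientation or reversed order, or with a donor-coordinate jump
    inconsistent with the base gap.  Candidates from different alternates
    within ``merge_window`` are clustered into one call; an alternate is
    *consistent_with_base* at a call if a single block of it spans the
    junction with ``junction_flank`` on both sides; discrepant alternates
    agree when their discrepancy categories match within the cluster.
    """
    params = params or ReconcileParams()
    for alt_name, blocks in alignments.items():
        for b in blocks:
            if b.base_id not in base:
                raise ValueError(f"alignment of {alt_name!r} references unknown "
                                 f"base scaffold {b.base_id!r}")
    per_alt = {name: _blocks_by_scaffold(blocks) for name, blocks in alignments.items()}
    cands: list[JunctionCandidate] = []
    for name in sorted(per_alt):
        cands.extend(_junction_candidates(name, per_alt[name], params))
    gaps_by_scaf: dict[str, list[GapTract]] = {}
    for g in gaps:
        gaps_by_scaf.setdefault(g.scaffold_id, []).append(g)

    calls: list[BreakpointCall] = []
    by_scaf: dict[str, list[JunctionCandidate]] = {}
    for c in cands:
        by_scaf.setdefault(c.base_id, []).append(c)
    for base_id in sorted(by_scaf):
        clist = sorted(by_scaf[base_id], key=lambda c: c.pos)
        cluster: list[JunctionCandidate] = []
        for c in clist + [None]:  # type: ignore[list-item]
            if cluster and (c is None or c.pos - cluster[-1].pos > params.merge_window):
                calls.append(_make_call(base_id, cluster, per_alt,
                                        gaps_by_scaf.get(base_id, []), params))
                cluster = []
            if c is not None:
                cluster.append(c)
    calls.sort(key=lambda c: (c.base_id, c.position))
    return calls


def _make_call(base_id: str, cluster: list[JunctionCandidate],
               per_alt: dict[str, dict[str, list[AlignmentBlock]]],
               gaps: list[GapTract], params: ReconcileParams) -> BreakpointCall:
    positions = sorted(c.pos for c in cluster)
    pos = positions[len(positions) // 2]
    evidence: dict[str, str] = {}
    nearest: dict[str, JunctionCandidate] = {}
    for c in cluster:
        cur = nearest.get(c.alt_name)
        if cur is None or abs(c.pos - pos) < abs(cur.pos - pos):
            nearest[c.alt_name] = c
    for alt_name in sorted(per_alt):
        if alt_name in nearest:
            evidence[alt_name] = "discrepant"
            continue
        spans = any(
            b.base_start <= pos - params.junction_flank
            and b.base_end >= pos + params.junction_flank
            for b in per_alt[alt_name].get(base_id, ()))
        evidence[alt_name] = "consistent_with_base" if spans else "no_coverage"
    by_cat: dict[str, list[str]] = {}
    for alt_name, cand in nearest.items():
        by_cat.setdefault(cand.category, []).append(alt_name)
    best_cat, agreeing = max(by_cat.items(), key=lambda kv: (len(kv[1]), kv[0])) \
        if by_cat else ("", [])
    gap_nearby = any(g.end >= pos - params.gap_window and g.start <= pos + params.gap_window
                     for g in gaps)
    return BreakpointCall(
        base_id=base_id, position=pos, gap_nearby=gap_nearby,
        evidence=evidence, n_discrepant_agreeing=len(agreeing),
        agreeing_alts=sorted(agreeing), category=best_cat,
        candidates=nearest)


def write_calls_bed(calls: list[BreakpointCall], path) -> None:
    """Breakpoint calls as BED (0-based half-open) on the base assembly."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            name = f"call{i}:{c.category}:{'actionable' if c.actionable else 'not_actionable'}"
            fh.write(f"{c.base_id}\t{c.position}\t{c.position + 1}\t{name}\t"
                     f"{c.n_discrepant_agreeing}\t.\n")


# ---------------------------------------------------------------------------
# Block replacement
# ---------------------------------------------------------------------------

def _find_repair(call: BreakpointCall, alt_name: str,
                 per_scaffold: list[AlignmentBlock],
                 params: ReconcileParams):
    """Find the donor interval repairing ``call`` using alternate
    ``alt_name``: from the discrepant junction's left block, the first
    downstream block of the same donor contig/strand with advancing donor
    coordinates bounds the replacement.  Returns (u, v, alt_id, strand)
    anchor tuples or None."""
    cand = call.candidates.get(alt_name)
    if cand is None:
        return None
    # forward: from the junction's left block, first downstream block of the
    # same donor contig whose trusted anchors give a non-negative (possibly
    # empty — a pure excision) donor interval
    b1 = cand.left
    ua = _last_anchor(b1, params.min_event_anchor)
    if ua is not None:
        u = _inner_edge(ua, b1.strand)
        for b in per_scaffold:
            if b.base_start < b1.base_end or b is b1:
                continue
            if b.base_start - b1.base_end > params.max_replace_span:
                break
            if b.alt_id != b1.alt_id or b.strand != b1.strand:
                continue
            v = _first_anchor_after(b, u[0], params.min_event_anchor)
            if v is None:
                continue
            ds, de = _donor_interval(b1.strand, u, v)
            if de >= ds:
                return u, v, b1.alt_id, b1.strand, ds, de
    # mirrored: from the junction's right block, nearest upstream block of
    # the same donor contig (covers the right-hand junction of an event
    # whose left block maps elsewhere)
    b2 = cand.right
    for b in reversed(per_scaffold):
        if b.base_end > b2.base_start or b is b2:
            continue
        if b2.base_start - b.base_end > params.max_replace_span:
            break
        if b.alt_id != b2.alt_id or b.strand != b2.strand:
            continue
        ua = _last_anchor(b, params.min_event_anchor)
        if ua is None:
            continue
        u = _inner_edge(ua, b2.strand)
        v = _first_anchor_after(b2, u[0], params.min_event_anchor)
        if v is None:
            continue
        ds, de = _donor_interval(b2.strand, u, v)
        if de >= ds:
            return u, v, b2.alt_id, b2.strand, ds, de
    return None


def apply_block_replacements(base: AssemblySet,
                             alignments: dict[str, list[AlignmentBlock]],
                             calls: list[BreakpointCall],
                             rng_seed: int = 0,
                             params: ReconcileParams | None = None,
                             alt_assemblies: dict[str, AssemblySet] | None = None,
                             ) -> tuple[AssemblySet, list[EditRecord]]:
    """Replace the region around each actionable call with a donor interval.

    The donor is chosen by seeded RNG among the agreeing alternates that can
    supply a contiguous interval (the random draw is recorded); replacement
    sequence is reverse-complemented for '-' donors.  Edits are applied
    right-to-left within each scaffold so pre-edit coordinates stay valid;
    calls whose region overlaps an already-accepted edit, or for which no
    donor anchors are found, are skipped with a warning.
    """
    params = params or ReconcileParams()
    if alt_assemblies is None:
        raise ValueError("alt_assemblies mapping (name -> AssemblySet) is required "
                         "to extract donor sequence")
    rng = random.Random(f"{rng_seed}:block_replacement")
    per_alt = {name: _blocks_by_scaffold(blocks) for name, blocks in alignments.items()}
    actionable = [c for c in calls if c.actionable]
    # largest evidence first, ties leftmost
    actionable.sort(key=lambda c: (-c.n_discrepant_agreeing, c.base_id, c.position))
    accepted: dict[str, list[tuple[int, int, EditRecord]]] = {}
    trees: dict[str, IntervalTree] = {}
    n_skipped = 0
    for call in actionable:
        options = []
        for alt_name in call.agreeing_alts:
            rep = _find_repair(call, alt_name,
                               per_alt[alt_name].get(call.base_id, []), params)
            if rep is not None:
                options.append((alt_name, rep))
        if not options:
            log.warning("call at %s:%d skipped: no donor anchors found",
                        call.base_id, call.position)
            n_skipped += 1
            continue
        draw = rng.randrange(len(options))
        alt_name, (u, v, alt_id, strand, ds, de) = options[draw]
        start, end = u[0], v[0]
        tree = trees.setdefault(call.base_id, IntervalTree())
        if tree.overlap(start, end):
            n_skipped += 1
            continue
        tree.addi(start, end)
        rec = EditRecord(
            kind="block_replacement", base_id=call.base_id,
            base_start=start, base_end=end,
            donor_assembly=alt_name, donor_id=alt_id,
            donor_start=ds, donor_end=de, donor_strand=strand,
            inserted_length=de - ds, rng_draw=draw)
        accepted.setdefault(call.base_id, []).append((start, end, rec))
    hybrid = base.copy()
    edits: list[EditRecord] = []
    for scaf_id, lst in accepted.items():
        for start, end, rec in sorted(lst, key=lambda t: -t[0]):
            donor_seq = alt_assemblies[rec.donor_assembly][rec.donor_id] \
                .sequence[rec.donor_start:rec.donor_end]
            if rec.donor_strand == "-":
                donor_seq = reverse_complement(donor_seq)
            _splice(hybrid, scaf_id, start, end, donor_seq,
                    [SeqComponent(rec.donor_assembly, rec.donor_id,
                                  rec.donor_start, rec.donor_end, rec.donor_strand)])
            edits.append(rec)
    edits.sort(key=lambda e: (e.base_id, e.base_start))
    hybrid._n_skipped_calls = n_skipped  # type: ignore[attr-defined]
    return hybrid, edits


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def fill_gaps(base: AssemblySet, gaps: list[GapTract],
              alignments: dict[str, list[AlignmentBlock]],
              params: ReconcileParams | None = None,
              rng_seed: int = 0,
              alt_assemblies: dict[str, AssemblySet] | None = None,
              ) -> tuple[AssemblySet, list[EditRecord], dict]:
    """Fill N-gaps from gap-free alternate intervals.

    A gap is fillable by an alternate iff one of its blocks spans the gap
    with at least ``flank`` bp of aligned sequence on both sides, anchors
    exist within ``max_anchor_dist`` of the gap edges, and the donor
    interval contains no N.  Among eligible alternates one is chosen by
    seeded RNG.  Overlapping fill intervals from the same donor block merge
    into one combined edit; overlapping intervals from different donors
    keep the leftmost and skip the rest.
    """
    params = params or ReconcileParams()
    if alt_assemblies is None:
        raise ValueError("alt_assemblies mapping is required")
    rng = random.Random(f"{rng_seed}:gap_fill")
    per_alt = {name: _blocks_by_scaffold(blocks) for name, blocks in alignments.items()}
    gaps = sorted(gaps, key=lambda g: (g.scaffold_id, g.start))
    # pending edits per scaffold: (start, end, alt_name, block, u, v)
    pending: dict[str, list[dict]] = {}
    n_unfillable = 0
    for gap in gaps:
        lst = pending.setdefault(gap.scaffold_id, [])
        if lst and lst[-1]["start"] <= gap.start < lst[-1]["end"]:
            lst[-1]["gaps"].append(gap)  # already inside the previous fill
            continue
        options = []
        for alt_name in sorted(per_alt):
            for b in per_alt[alt_name].get(gap.scaffold_id, ()):
                if b.base_start > gap.start - params.flank:
                    continue
                if b.base_end < gap.end + params.flank:
                    continue
                u, v = _anchors_flanking_gap(b, gap, params.min_event_anchor)
                if u is None or v is None:
                    continue
                if gap.start - (u[0] + u[2]) > params.max_anchor_dist:
                    continue
                if v[0] - gap.end > params.max_anchor_dist:
                    continue
                u = _inner_edge(u, b.strand)
                ds, de = _donor_interval(b.strand, u, v)
                if de < ds:  # empty donor = pure N removal, still a valid fill
                    continue
                donor_seq = alt_assemblies[alt_name][b.alt_id].sequence[ds:de]
                if "N" in donor_seq:
                    continue
                options.append({"alt": alt_name, "block": b, "u": u, "v": v,
                                "ds": ds, "de": de})
        if not options:
            n_unfillable += 1
            continue
        prev = lst[-1] if lst else None
        if prev is not None and any(o["u"][0] < prev["end"] for o in options):
            same = [o for o in options
                    if o["block"] is prev["block"] and o["v"][0] > prev["end"]]
            if same:
                o = same[0]  # extend the previous combined edit
                prev["v"] = o["v"]
                prev["end"] = o["v"][0]
                ds, de = _donor_interval(o["block"].strand, prev["u"], o["v"])
                prev["ds"], prev["de"] = ds, de
                prev["gaps"].append(gap)
                continue
            options = [o for o in options if o["u"][0] >= prev["end"]]
            if not options:
                n_unfillable += 1
                continue
        draw = rng.randrange(len(options))
        o = options[draw]
        lst.append({"start": o["u"][0], "end": o["v"][0], "alt": o["alt"],
                    "block": o["block"], "u": o["u"], "v": o["v"],
                    "ds": o["ds"], "de": o["de"], "draw": draw, "gaps": [gap]})
    hybrid = base.copy()
    edits: list[EditRecord] = []
    n_filled = 0
    filled_len = 0
    for scaf_id, lst in pending.items():
        for e in sorted(lst, key=lambda d: -d["start"]):
            b = e["block"]
            donor_seq = alt_assemblies[e["alt"]][b.alt_id].sequence[e["ds"]:e["de"]]
            if b.strand == "-":
                donor_seq = reverse_complement(donor_seq)
            _splice(hybrid, scaf_id, e["start"], e["end"], donor_seq,
                    [SeqComponent(e["alt"], b.alt_id, e["ds"], e["de"], b.strand)])
            edits.append(EditRecord(
                kind="gap_fill", base_id=scaf_id,
                base_start=e["start"], base_end=e["end"],
                donor_assembly=e["alt"], donor_id=b.alt_id,
                donor_start=e["ds"], donor_end=e["de"], donor_strand=b.strand,
                inserted_length=e["de"] - e["ds"], rng_draw=e["draw"]))
            n_filled += len(e["gaps"])
            filled_len += sum(g.length for g in e["gaps"])
    edits.sort(key=lambda e: (e.base_id, e.base_start))
    summary = {"n_gaps_filled": n_filled, "filled_gap_total_length": filled_len,
               "n_gaps_unfillable": n_unfillable}
    return hybrid, edits, summary


# ---------------------------------------------------------------------------
# Scaffold merging
# ---------------------------------------------------------------------------

def merge_scaffolds(base: AssemblySet,
                    alignments: dict[str, list[AlignmentBlock]],
                    params: ReconcileParams | None = None,
                    ) -> tuple[AssemblySet, list[EditRecord]]:
    """Merge scaffold pairs whose adjacency is attested by alternate contigs.

    Scaffolds A and B (each >= ``min_merge_len``) are merged when at least
    ``min_merge_evidence`` alternates each contain a single contig whose
    blocks cover a terminal window of one end of A and one end of B
    collinearly; orientations are resolved from the block strands and the
    halves are joined across ``join_gap_len`` N.  Conflicting evidence for
    one scaffold end vetoes its merges.
    """
    params = params or ReconcileParams()
    slen = base.lengths()
    eligible = {sid for sid, l in slen.items() if l >= params.min_merge_len}
    # votes: (idA, endA, idB, endB) canonical -> set of alternates
    votes: dict[tuple[str, str, str, str], set[str]] = {}
    for alt_name in sorted(alignments):
        by_contig: dict[str, list[AlignmentBlock]] = {}
        for b in alignments[alt_name]:
            if b.base_id in eligible:
                by_contig.setdefault(b.alt_id, []).append(b)
        for contig, blocks in sorted(by_contig.items()):
            touched: list[tuple[str, str, AlignmentBlock]] = []
            for b in blocks:
                l = slen[b.base_id]
                if b.base_start <= params.terminal_window:
                    touched.append((b.base_id, "L", b))
                if b.base_end >= l - params.terminal_window:
                    touched.append((b.base_id, "R", b))
            seen_scafs = {t[0] for t in touched}
            if len(seen_scafs) != 2:
                continue
            ends: dict[str, tuple[str, AlignmentBlock]] = {}
            for sid, endc, b in touched:
                ends[sid] = (endc, b)
            (sidA, (eA, bA)), (sidB, (eB, bB)) = sorted(ends.items())
            # both blocks must sit on one contig with disjoint donor intervals
            lo, hi = sorted([(bA.alt_start, bA.alt_end, "A"), (bB.alt_start, bB.alt_end, "B")])
            if lo[1] > hi[0]:
                continue
            # walking the contig forward must exit the first scaffold through
            # its touched end and enter the second through its touched end
            first, second = (("A", eA, bA), ("B", eB, bB)) if lo[2] == "A" \
                else (("B", eB, bB), ("A", eA, bA))
            _, e1, b1 = first
            _, e2, b2 = second
            exit_ok = (e1 == "R") == (b1.strand == "+")
            entry_ok = (e2 == "L") == (b2.strand == "+")
            if not (exit_ok and entry_ok):
                continue
            votes.setdefault((sidA, eA, sidB, eB), set()).add(alt_name)
    winners = {key: alts for key, alts in votes.items()
               if len(alts) >= params.min_merge_evidence}
    # conflicts: one scaffold end supporting two different partners
    end_use: dict[tuple[str, str], list] = {}
    for key in winners:
        sidA, eA, sidB, eB = key
        end_use.setdefault((sidA, eA), []).append(key)
        end_use.setdefault((sidB, eB), []).append(key)
    conflicted = {k for ks in end_use.values() if len(ks) > 1 for k in ks}
    for key in sorted(conflicted):
        log.warning("conflicting merge evidence for %s:%s — %s:%s; no merge", *key)
    merges = sorted(set(winners) - conflicted)

    out = base.copy()
    edits: list[EditRecord] = []
    used: set[str] = set()
    for sidA, eA, sidB, eB in merges:
        if sidA in used or sidB in used:
            continue  # chained merges: one round, first come first served
        used.update((sidA, sidB))
        a, b = out[sidA], out[sidB]
        comps_a = out.provenance[sidA]
        comps_b = out.provenance[sidB]
        seq_a, seq_b = a.sequence, b.sequence
        orient_b = "+"
        if eA == "L":  # flip A so its touched end is on the right
            seq_a = reverse_complement(seq_a)
            comps_a = [_flip(c) for c in reversed(comps_a)]
            eA = "R"
        if eB == "R":  # flip B so its touched end is on the left
            seq_b = reverse_complement(seq_b)
            comps_b = [_flip(c) for c in reversed(comps_b)]
            orient_b = "-"
        merged_id = f"{sidA}+{sidB}"
        gap = "N" * params.join_gap_len
        out.remove(sidA)
        out.remove(sidB)
        out.add(Scaffold(merged_id, seq_a + gap + seq_b),
                comps_a + [GapComponent(params.join_gap_len)] + comps_b)
        edits.append(EditRecord(
            kind="merge", base_id=sidA, base_start=a.length, base_end=a.length,
            donor_assembly=base.name, donor_id=sidB,
            donor_start=0, donor_end=b.length, donor_strand=orient_b,
            inserted_length=params.join_gap_len + b.length))
    return out, edits


def _flip(c: Component) -> Component:
    if isinstance(c, GapComponent):
        return c
    return SeqComponent(c.assembly, c.seq_id, c.start, c.end,
                        "-" if c.strand == "+" else "+")


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _align_all(base: AssemblySet, alts: dict[str, AssemblySet],
               params: ReconcileParams) -> dict[str, list[AlignmentBlock]]:
    from .alignment import align_to_all
    return align_to_all(base, alts, params.align)


def reconcile_pipeline(base: AssemblySet, alts: dict[str, AssemblySet],
                       params: ReconcileParams | None = None,
                       seed: int = 0, do_merge: bool = True,
                       alignments: dict[str, list[AlignmentBlock]] | None = None,
                       ) -> tuple[AssemblySet, ReconcileReport, list[BreakpointCall]]:
    """Run align -> call_breakpoints -> block replacement -> gap fill
    (-> merge) and return the hybrid assembly, the report and the calls.

    Requires >= 2 alternates: the consensus check needs two agreeing
    alternates.  Pre-computed ``alignments`` (e.g. from PAF) may be passed
    for the first round; later rounds re-align against the edited assembly.
    """
    params = params or ReconcileParams()
    if len(alts) < 2:
        raise ValueError(
            "at least 2 alternate assemblies are required: misjoin calling "
            "demands two alternates that are mutually consistent and "
            "discrepant with the base")
    report = ReconcileReport()
    if alignments is None:
        alignments = _align_all(base, alts, params)
    gaps = find_gaps(base)
    calls = call_breakpoints(base, gaps, alignments, params)
    report.n_breakpoints_called = len(calls)
    report.n_actionable = sum(c.actionable for c in calls)
    hybrid, rep_edits = apply_block_replacements(
        base, alignments, calls, rng_seed=seed, params=params, alt_assemblies=alts)
    report.n_blocks_replaced = len(rep_edits)
    report.n_calls_skipped = getattr(hybrid, "_n_skipped_calls", 0)
    report.edits.extend(rep_edits)

    if rep_edits:
        alignments = _align_all(hybrid, alts, params)
    gaps = find_gaps(hybrid)
    hybrid, fill_edits, summary = fill_gaps(
        hybrid, gaps, alignments, params, rng_seed=seed, alt_assemblies=alts)
    report.n_gaps_filled = summary["n_gaps_filled"]
    report.filled_gap_total_length = summary["filled_gap_total_length"]
    report.n_gaps_unfillable = summary["n_gaps_unfillable"]
    report.edits.extend(fill_edits)

    if do_merge:
        if fill_edits or rep_edits:
            alignments = _align_all(hybrid, alts, params)
        hybrid, merge_edits = merge_scaffolds(hybrid, alignments, params)
        report.n_merges = len(merge_edits)
        report.edits.extend(merge_edits)
    return hybrid, report, calls
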