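"""Long-insert (BAC-end) read-pair concordance validation.

BAC clones carry ~100-200 kb inserts; end-sequenced pairs that align to one
scaffold, inward-facing, at a plausible insert size validate long-range
assembly structure.  Comparing concordance counts before and after
reconciliation measures whether edits improved that structure.

Pairs can come from SAM/BAM (primary alignments only, via pysam) or from a
simple 9-column TSV so the module is testable without an aligner:
``pair_id  id1  pos1  strand1  mapq1  id2  pos2  strand2  mapq2``
(``*`` marks an unmapped end, positions 0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from collections import Counter

DEFAULT_MIN_INSERT = 20_000
DEFAULT_MAX_INSERT = 300_000


@dataclass(frozen=True)
class End:
    """One end of a pair: ``scaffold is None`` means unmapped."""

    scaffold: str | None
    pos: int
    strand: str
    mapq: int
    length: int = 150


@dataclass(frozen=True)
class PairAlignment:
    pair_id: str
    end1: End
    end2: End


@dataclass(frozen=True)
class PairClass:
    pair_id: str
    verdict: str  # concordant | discordant | single_end | unaligned
    insert_size: int | None
    reason: str  # ok | different_scaffold | same_strand | outward_facing | insert_out_of_range | low_mapq | unmapped


def classify_pairs(pairs: list[PairAlignment],
                   min_insert: int = DEFAULT_MIN_INSERT,
                   max_insert: int = DEFAULT_MAX_INSERT,
                   min_mapq: int = 0) -> list[PairClass]:
    """Classify each pair as concordant / discordant / single_end / unaligned.

    Concordant requires: both ends mapped with mapq >= ``min_mapq``, on the
    same scaffold, in inward-facing forward-reverse orientation, with outer
    insert size within [min_insert, max_insert].
    """
    if min_insert >= max_insert:
        raise ValueError("min_insert must be < max_insert")
    seen: dict[str, PairAlignment] = {}
    for p in pairs:
        if p.pair_id in seen and seen[p.pair_id] != p:
            raise ValueError(f"duplicate pair_id with conflicting records: {p.pair_id!r}")
        seen[p.pair_id] = p
    out: list[PairClass] = []
    for p in pairs:
        mapped = [e for e in (p.end1, p.end2) if e.scaffold is not None]
        if len(mapped) == 0:
            out.append(PairClass(p.pair_id, "unaligned", None, "unmapped"))
            continue
        if len(mapped) == 1:
            out.append(PairClass(p.pair_id, "single_end", None, "unmapped"))
            continue
        e1, e2 = p.end1, p.end2
        left, right = (e1, e2) if e1.pos <= e2.pos else (e2, e1)
        insert = right.pos + right.length - left.pos
        if e1.scaffold != e2.scaffold:
            out.append(PairClass(p.pair_id, "discordant", None, "different_scaffold"))
        elif e1.mapq < min_mapq or e2.mapq < min_mapq:
            out.append(PairClass(p.pair_id, "discordant", insert, "low_mapq"))
        elif e1.strand == e2.strand:
            out.append(PairClass(p.pair_id, "discordant", insert, "same_strand"))
        elif not (left.strand == "+" and right.strand == "-"):
            out.append(PairClass(p.pair_id, "discordant", insert, "outward_facing"))
        elif not (min_insert <= insert <= max_insert):
            out.append(PairClass(p.pair_id, "discordant", insert, "insert_out_of_range"))
        else:
            out.append(PairClass(p.pair_id, "concordant", insert, "ok"))
    return out


# ---------------------------------------------------------------------------
# Before/after comparison
# ---------------------------------------------------------------------------

VERDICTS = ("concordant", "discordant", "single_end", "unaligned")


@dataclass
class DeltaReport:
    counts_a: dict[str, int]
    counts_b: dict[str, int]
    deltas: dict[str, int]  # B - A
    changed: list[dict]     # pair_id, verdict_a, verdict_b, reason_a, reason_b

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("verdict\tcount_a\tcount_b\tdelta\n")
            for v in VERDICTS:
                fh.write(f"{v}\t{self.counts_a[v]}\t{self.counts_b[v]}\t{self.deltas[v]}\n")


def compare_assemblies(classes_a: list[PairClass],
                       classes_b: list[PairClass]) -> DeltaReport:
    """Per-verdict counts for assemblies A and B, deltas (B - A) and the
    pairs whose verdict changed.  Both class lists must cover the same
    pair_id universe."""
    a = {c.pair_id: c for c in classes_a}
    b = {c.pair_id: c for c in classes_b}
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:3]
        only_b = sorted(set(b) - set(a))[:3]
        raise ValueError(f"pair universes differ (e.g. only in A: {only_a}, only in B: {only_b})")
    ca = Counter(c.verdict for c in classes_a)
    cb = Counter(c.verdict for c in classes_b)
    counts_a = {v: ca.get(v, 0) for v in VERDICTS}
    counts_b = {v: cb.get(v, 0) for v in VERDICTS}
    changed = [
        {"pair_id": pid, "verdict_a": a[pid].verdict, "verdict_b": b[pid].verdict,
         "reason_a": a[pid].reason, "reason_b": b[pid].reason}
        for pid in sorted(a) if a[pid].verdict != b[pid].verdict
    ]
    return DeltaReport(
        counts_a=counts_a, counts_b=counts_b,
        deltas={v: counts_b[v] - counts_a[v] for v in VERDICTS},
        changed=changed)


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

def read_pairs_tsv(path) -> list[PairAlignment]:
    """Read the 9-column pair TSV dialect (optional ``length`` 10th column)."""
    pairs: dict[str, PairAlignment] = {}
    out: list[PairAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("pair_id\t"):
                continue
            f = line.split("\t")
            if len(f) not in (9, 10):
                raise ValueError(f"{path}: line {lineno}: expected 9 or 10 columns, got {len(f)}")
            length = int(f[9]) if len(f) == 10 else 150

            def _end(i):
                if f[i] == "*":
                    return End(None, -1, ".", 0, length)
                return End(f[i], int(f[i + 1]), f[i + 2], int(f[i + 3]), length)

            p = PairAlignment(f[0], _end(1), _end(5))
            if p.pair_id in pairs and pairs[p.pair_id] != p:
                raise ValueError(f"{path}: duplicate pair_id with conflicting records: {p.pair_id!r}")
            if p.pair_id not in pairs:
                out.append(p)
            pairs[p.pair_id] = p
    return out


def write_pairs_tsv(pairs: list[PairAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tid1\tpos1\tstrand1\tmapq1\tid2\tpos2\tstrand2\tmapq2\tlength\n")
        for p in pairs:
            row = [p.pair_id]
            for e in (p.end1, p.end2):
                if e.scaffold is None:
                    row += ["*", "-1", ".", "0"]
                else:
                    row += [e.scaffold, str(e.pos), e.strand, str(e.mapq)]
            row.append(str(p.end1.length))
            fh.write("\t".join(row) + "\n")


def read_pairs_sam(path) -> list[PairAlignment]:
    """Read primary alignments of paired reads from SAM/BAM via pysam.

    Secondary and supplementary records are ignored; each pair must have at
    most one primary record per end.
    """
    import pysam

    ends: dict[str, dict[int, End]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            which = 2 if rec.is_read2 else 1
            if rec.is_unmapped:
                end = End(None, -1, ".", 0, rec.query_length or 150)
            else:
                end = End(rec.reference_name, rec.reference_start,
                          "-" if rec.is_reverse else "+", rec.mapping_quality,
                          rec.query_length or rec.infer_query_length() or 150)
            slot = ends.setdefault(rec.query_name, {})
            if which in slot and slot[which] != end:
                raise ValueError(f"duplicate primary record for {rec.query_name!r} end {which}")
            slot[which] = end
    missing = End(None, -1, ".", 0, 150)
    return [PairAlignment(name, slot.get(1, missing), slot.get(2, missing))
            for name, slot in ends.items()]
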