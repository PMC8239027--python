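"""Strand-aware alignment blocks between a base assembly and alternates.

The built-in aligner is a minimizer-anchor + sparse-chaining pipeline, the
classical seed-and-chain design: sample window minimizers from the alternate
contigs into an exact k-mer index, look up the base scaffold's minimizers,
merge co-diagonal overlapping hits into maximal exact-match runs, and chain
runs with a collinearity dynamic programme.  There is deliberately no
base-level (CIGAR) alignment: the unit of reconciliation is the block, and
edit boundaries snap to anchors, where base and alternate agree exactly.

Pre-computed alignments from an external aligner can be substituted via
:func:`read_paf`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

from .assembly_io import AssemblySet, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_K = 15
DEFAULT_WINDOW = 10
DEFAULT_GAP_LIMIT = 10_000
DEFAULT_MIN_BLOCK_LEN = 500
DEFAULT_MAX_OCC = 50
DEFAULT_MAX_INDEL_RATIO = 1.25


@dataclass(frozen=True)
class Anchor:
    """An exact match of ``k`` bp between base and alternate.

    ``alt_pos`` is always on the forward strand of the alternate contig; for
    a ``-`` anchor, ``base[base_pos : base_pos+k]`` equals the reverse
    complement of ``alt[alt_pos : alt_pos+k]``.  Runs of overlapping
    co-diagonal seed matches are merged, so ``k`` can exceed the seed size.
    """

    base_pos: int
    alt_pos: int
    k: int
    strand: str


@dataclass
class AlignmentBlock:
    """A chained, strand-consistent interval pair (0-based half-open)."""

    base_id: str
    base_start: int
    base_end: int
    alt_assembly_name: str
    alt_id: str
    alt_start: int
    alt_end: int
    strand: str
    n_anchors: int
    score: int
    base_len: int = 0
    alt_len: int = 0
    mapq: int = 60
    aln_len: int = 0
    anchors: list[Anchor] | None = field(default=None, repr=False)

    @property
    def base_span(self) -> int:
        return self.base_end - self.base_start

    @property
    def alt_span(self) -> int:
        return self.alt_end - self.alt_start


# ---------------------------------------------------------------------------
# Minimizer extraction (vectorized)
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _minimizers(seq: str, k: int, window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window minimizers of ``seq``.

    Returns (positions, canonical codes, forward-strand flags).  K-mers
    containing non-ACGT characters are excluded.  Canonical code is the
    smaller of the forward and reverse-complement 2-bit encodings, so code
    equality implies exact sequence match (no hashing collisions).
    """
    n = len(seq)
    if n < k:
        return (np.empty(0, np.int64),) * 3  # type: ignore[return-value]
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.int64)
    rev = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for i in range(k):
        col = arr[i:i + m]
        bad |= col < 0
        fwd = (fwd << 2) | (col & 3)
        rev |= (3 - (col & 3)) << (2 * i)
    canon = np.minimum(fwd, rev)
    is_fwd = fwd <= rev
    sentinel = np.int64(1) << 62
    canon_m = np.where(bad, sentinel, canon)
    w = min(window, m)
    if w <= 1:
        pos = np.nonzero(~bad)[0]
        return pos, canon[pos], is_fwd[pos]
    from numpy.lib.stride_tricks import sliding_window_view
    if k <= 15:  # 2k bits fit int32; argmin is markedly faster
        canon_m = np.where(bad, np.int32(2**31 - 1), canon.astype(np.int32))
    sw = sliding_window_view(canon_m, w)
    pos = np.unique(sw.argmin(axis=1) + np.arange(sw.shape[0]))
    keep = ~bad[pos]
    pos = pos[keep]
    return pos, canon[pos], is_fwd[pos]


class AnchorIndex:
    """Minimizer index over an alternate assembly's contigs."""

    def __init__(self, alt: AssemblySet, k: int = DEFAULT_K,
                 window: int = DEFAULT_WINDOW, max_occ: int = DEFAULT_MAX_OCC):
        if not 11 <= k <= 31:
            raise ValueError("k must be in [11, 31]")
        if window < 1:
            raise ValueError("window must be >= 1")
        if all(s.length < k for s in alt):
            raise ValueError(f"k={k} exceeds the length of every contig")
        self.k, self.window, self.max_occ = k, window, max_occ
        self.alt_name = alt.name
        self.contig_ids = alt.ids
        self.contig_lengths = [alt[c].length for c in self.contig_ids]
        codes_all, pos_all, fwd_all, cid_all = [], [], [], []
        for ci, cid in enumerate(self.contig_ids):
            pos, codes, is_fwd = _minimizers(alt[cid].sequence, k, window)
            codes_all.append(codes)
            pos_all.append(pos)
            fwd_all.append(is_fwd)
            cid_all.append(np.full(len(pos), ci, dtype=np.int64))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = np.concatenate(pos_all)[order] if codes_all else np.empty(0, np.int64)
        self._fwd = np.concatenate(fwd_all)[order] if codes_all else np.empty(0, bool)
        self._cid = np.concatenate(cid_all)[order] if codes_all else np.empty(0, np.int64)
        # repeat filter: mask codes occurring more than max_occ times
        uniq, starts, counts = np.unique(self._codes, return_index=True, return_counts=True)
        repetitive = uniq[counts > max_occ]
        self._repetitive = set(repetitive.tolist())
        if len(repetitive):
            log.debug("%s: %d repetitive minimizer codes dropped", alt.name, len(repetitive))

    def lookup(self, code: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All (contig index, position, fwd flag) occurrences of ``code``."""
        if code in self._repetitive:
            e = np.empty(0, np.int64)
            return e, e, np.empty(0, bool)
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._cid[lo:hi], self._pos[lo:hi], self._fwd[lo:hi]


def index_anchors(alt: AssemblySet, k: int = DEFAULT_K, window: int = DEFAULT_WINDOW,
                  max_occ: int = DEFAULT_MAX_OCC) -> AnchorIndex:
    """Build a minimizer-style sampled k-mer index over alternate contigs."""
    return AnchorIndex(alt, k=k, window=window, max_occ=max_occ)


# ---------------------------------------------------------------------------
# Anchor collection and run merging
# ---------------------------------------------------------------------------

def _collect_raw_anchors(base_seq: str, index: AnchorIndex, minimizers=None):
    """Match base minimizers against the index (fully vectorized).

    Returns arrays (contig idx, strand flag [True = '+'], base pos, alt pos).
    Query codes matching more than ``max_occ`` index positions are dropped
    as repetitive.  ``minimizers`` may carry pre-computed base minimizers.
    """
    if minimizers is None:
        minimizers = _minimizers(base_seq, index.k, index.window)
    pos, codes, is_fwd = minimizers
    empty = (np.empty(0, np.int64), np.empty(0, bool),
             np.empty(0, np.int64), np.empty(0, np.int64))
    if len(pos) == 0 or len(index._codes) == 0:
        return empty
    lo = np.searchsorted(index._codes, codes, side="left")
    hi = np.searchsorted(index._codes, codes, side="right")
    cnt = hi - lo
    keep = (cnt > 0) & (cnt <= index.max_occ)
    if not keep.any():
        return empty
    starts, counts = lo[keep], cnt[keep]
    total = int(counts.sum())
    idx = np.repeat(starts, counts) + (
        np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts))
    ci = index._cid[idx]
    ap = index._pos[idx]
    st = index._fwd[idx] == np.repeat(is_fwd[keep], counts)
    bp = np.repeat(pos[keep], counts)
    return ci, st, bp, ap


def _merge_runs(ci, st, bp, ap, k: int, contig_lengths) -> dict[tuple[int, str], list[Anchor]]:
    """Merge overlapping co-diagonal seed matches into maximal exact runs.

    Two consecutive seeds on one diagonal merge when the base advance is at
    most k (overlapping exact matches imply the union is an exact match).
    Returns merged anchors grouped by (contig index, strand).
    """
    groups: dict[tuple[int, str], list[Anchor]] = {}
    if len(ci) == 0:
        return groups
    lens = np.asarray(contig_lengths, dtype=np.int64)
    # transformed alt coordinate: forward position for '+', mirrored for '-'
    alt_t = np.where(st, ap, lens[ci] - k - ap)
    diag = bp - alt_t
    order = np.lexsort((bp, diag, st.astype(np.int64), ci))
    ci, st, bp, ap = (a[order] for a in (ci, st, bp, ap))
    diag = diag[order]
    n = len(ci)
    boundary = np.ones(n, dtype=bool)
    boundary[1:] = (
        (ci[1:] != ci[:-1]) | (st[1:] != st[:-1])
        | (diag[1:] != diag[:-1]) | (bp[1:] - bp[:-1] > k)
    )
    starts = np.flatnonzero(boundary)
    ends = np.empty_like(starts)
    ends[:-1] = starts[1:] - 1
    ends[-1] = n - 1
    for s, e in zip(starts.tolist(), ends.tolist()):
        b0, b1 = int(bp[s]), int(bp[e])
        length = b1 - b0 + k
        strand = "+" if st[s] else "-"
        a0 = int(ap[s]) if strand == "+" else int(ap[e])
        groups.setdefault((int(ci[s]), strand), []).append(Anchor(b0, a0, length, strand))
    return groups


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def _alt_t(anchor: Anchor, alt_len: int) -> int:
    """Start of the anchor on the strand-normalized alternate axis (both
    axes advance together along a collinear chain)."""
    if anchor.strand == "+":
        return anchor.alt_pos
    return alt_len - (anchor.alt_pos + anchor.k)


def chain_anchors(anchors: list[Anchor], gap_limit: int = DEFAULT_GAP_LIMIT,
                  min_score: int = 0, alt_len: int | None = None) -> list[list[Anchor]]:
    """Maximal-score collinear chains by sparse dynamic programming.

    All anchors must share one (base scaffold, alternate contig, strand)
    triple.  Successive anchors must advance on both axes, with per-axis
    gap (next start minus previous end) at most ``gap_limit``; a chain's
    score is its summed anchor length.  Chains are extracted best-first;
    chains scoring below ``min_score`` are discarded.  Returns the anchor
    lists of the accepted chains (base order).
    """
    if not anchors:
        return []
    strands = {a.strand for a in anchors}
    if len(strands) != 1:
        raise ValueError("chain_anchors expects anchors of a single strand")
    if alt_len is None:
        # only needed to mirror '-' coordinates; infer an upper bound
        alt_len = max(a.alt_pos + a.k for a in anchors)
    idx = sorted(range(len(anchors)), key=lambda i: (anchors[i].base_pos, _alt_t(anchors[i], alt_len)))
    anchors = [anchors[i] for i in idx]
    b = np.array([a.base_pos for a in anchors], dtype=np.int64)
    t = np.array([_alt_t(a, alt_len) for a in anchors], dtype=np.int64)
    klen = np.array([a.k for a in anchors], dtype=np.int64)
    n = len(anchors)
    alive = np.ones(n, dtype=bool)
    chains: list[list[Anchor]] = []
    while alive.any():
        score = np.where(alive, klen, np.int64(-1))
        parent = np.full(n, -1, dtype=np.int64)
        act = np.nonzero(alive)[0]
        for pos_i, i in enumerate(act):
            js = act[:pos_i]
            if len(js) == 0:
                continue
            ok = (
                (b[js] < b[i]) & (t[js] < t[i])
                # ends must advance too: a shorter anchor contained in a
                # longer one is not a collinear successor
                & (b[js] + klen[js] < b[i] + klen[i])
                & (t[js] + klen[js] < t[i] + klen[i])
                & (b[i] - (b[js] + klen[js]) <= gap_limit)
                & (t[i] - (t[js] + klen[js]) <= gap_limit)
            )
            js = js[ok]
            if len(js) == 0:
                continue
            best = js[np.argmax(score[js])]
            if score[best] > 0:
                score[i] = klen[i] + score[best]
                parent[i] = best
        top = int(np.argmax(score))
        if score[top] < max(min_score, 1):
            break
        chain_idx = []
        cur = top
        while cur != -1:
            chain_idx.append(cur)
            cur = int(parent[cur])
        chain_idx.reverse()
        chains.append([anchors[i] for i in chain_idx])
        alive[chain_idx] = False
    chains.sort(key=lambda ch: ch[0].base_pos)
    return chains


def _chain_to_block(chain: list[Anchor], base_id: str, base_len: int,
                    alt_name: str, alt_id: str, alt_len: int) -> AlignmentBlock:
    strand = chain[0].strand
    b0 = chain[0].base_pos
    b1 = chain[-1].base_pos + chain[-1].k
    if strand == "+":
        a0 = chain[0].alt_pos
        a1 = chain[-1].alt_pos + chain[-1].k
    else:
        a0 = chain[-1].alt_pos
        a1 = chain[0].alt_pos + chain[0].k
    return AlignmentBlock(
        base_id=base_id, base_start=b0, base_end=b1,
        alt_assembly_name=alt_name, alt_id=alt_id, alt_start=a0, alt_end=a1,
        strand=strand, n_anchors=len(chain), score=sum(a.k for a in chain),
        base_len=base_len, alt_len=alt_len, aln_len=b1 - b0, anchors=chain,
    )


# ---------------------------------------------------------------------------
# Whole-assembly alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignParams:
    k: int = DEFAULT_K
    window: int = DEFAULT_WINDOW
    gap_limit: int = DEFAULT_GAP_LIMIT
    min_block_len: int = DEFAULT_MIN_BLOCK_LEN
    max_occ: int = DEFAULT_MAX_OCC
    max_indel_ratio: float = DEFAULT_MAX_INDEL_RATIO


def _trim_block(block: AlignmentBlock, keep_tree: IntervalTree,
                min_block_len: int) -> AlignmentBlock | None:
    """Trim a lower-priority block against already-kept base intervals.

    Edge overlaps are resolved by dropping/shrinking edge anchors; a kept
    interval strictly inside the block would split it, so the block is
    dropped instead.
    """
    hits = sorted(keep_tree.overlap(block.base_start, block.base_end))
    if not hits:
        return block
    lo, hi = block.base_start, block.base_end
    for iv in hits:
        if iv.begin <= lo:
            lo = max(lo, iv.end)
        elif iv.end >= hi:
            hi = min(hi, iv.begin)
        else:
            return None  # internal overlap: would split the block
    if hi - lo < min_block_len or block.anchors is None:
        return None
    new_chain: list[Anchor] = []
    for a in block.anchors:
        s, e = a.base_pos, a.base_pos + a.k
        if e <= lo or s >= hi:
            continue
        cut_l = max(0, lo - s)
        cut_r = max(0, e - hi)
        if a.k - cut_l - cut_r < 1:
            continue
        if a.strand == "+":
            new_chain.append(Anchor(s + cut_l, a.alt_pos + cut_l, a.k - cut_l - cut_r, "+"))
        else:
            new_chain.append(Anchor(s + cut_l, a.alt_pos + cut_r, a.k - cut_l - cut_r, "-"))
    if not new_chain:
        return None
    nb = _chain_to_block(new_chain, block.base_id, block.base_len,
                         block.alt_assembly_name, block.alt_id, block.alt_len)
    if nb.base_span < min_block_len:
        return None
    return nb


def _prune_shadow_anchors(anchors: list[Anchor]) -> list[Anchor]:
    """Drop anchors contained (on both axes) in a longer anchor of the same
    group — redundant shadows produced by tandem repeats."""
    if len(anchors) < 2:
        return anchors
    kept: list[Anchor] = []
    for a in sorted(anchors, key=lambda a: (-a.k, a.base_pos, a.alt_pos)):
        contained = any(
            b.base_pos <= a.base_pos and a.base_pos + a.k <= b.base_pos + b.k
            and b.alt_pos <= a.alt_pos and a.alt_pos + a.k <= b.alt_pos + b.k
            for b in kept)
        if not contained:
            kept.append(a)
    return kept


def align_assemblies(base: AssemblySet, alt: AssemblySet,
                     params: AlignParams | None = None,
                     _index: AnchorIndex | None = None,
                     _minimizer_cache: dict | None = None) -> list[AlignmentBlock]:
    """Align every base scaffold against an alternate assembly.

    Per (alternate contig, strand) the anchors are chained; overlapping
    blocks on the base are resolved by keeping the higher-score block and
    trimming the other (ties: longer block, then lexicographically smaller
    alternate contig id).  The result is sorted by (base_id, base_start)
    and is deterministic for identical inputs.
    """
    if len(base) == 0 or len(alt) == 0:
        raise ValueError("both assemblies must be non-empty")
    p = params or AlignParams()
    index = _index or index_anchors(alt, k=p.k, window=p.window, max_occ=p.max_occ)
    out: list[AlignmentBlock] = []
    for scaf in base:
        mins = None if _minimizer_cache is None else _minimizer_cache.get(scaf.id)
        if mins is None:
            mins = _minimizers(scaf.sequence, p.k, p.window)
            if _minimizer_cache is not None:
                _minimizer_cache[scaf.id] = mins
        ci, st, bp, ap = _collect_raw_anchors(scaf.sequence, index, mins)
        groups = _merge_runs(ci, st, bp, ap, p.k, index.contig_lengths)
        cand: list[AlignmentBlock] = []
        for (cidx, strand), anchors in sorted(groups.items()):
            if sum(a.k for a in anchors) < p.min_block_len:
                continue
            anchors = _prune_shadow_anchors(anchors)
            alt_id = index.contig_ids[cidx]
            alt_len = index.contig_lengths[cidx]
            for chain in chain_anchors(anchors, gap_limit=p.gap_limit,
                                       min_score=p.min_block_len, alt_len=alt_len):
                blk = _chain_to_block(chain, scaf.id, scaf.length,
                                      alt.name, alt_id, alt_len)
                if blk.base_span < p.min_block_len:
                    continue
                ratio = blk.alt_span / max(blk.base_span, 1)
                if not (1 / p.max_indel_ratio <= ratio <= p.max_indel_ratio):
                    continue
                cand.append(blk)
        cand.sort(key=lambda blk: (-blk.score, -blk.base_span, blk.alt_id, blk.base_start))
        keep_tree = IntervalTree()
        kept: list[AlignmentBlock] = []
        for blk in cand:
            trimmed = _trim_block(blk, keep_tree, p.min_block_len)
            if trimmed is None:
                continue
            keep_tree.addi(trimmed.base_start, trimmed.base_end)
            kept.append(trimmed)
        out.extend(kept)
    out.sort(key=lambda blk: (blk.base_id, blk.base_start, blk.alt_id))
    return out


def align_to_all(base: AssemblySet, alts: dict[str, AssemblySet],
                 params: AlignParams | None = None
                 ) -> dict[str, list[AlignmentBlock]]:
    """Align the base against several alternates, computing the base
    minimizers only once."""
    p = params or AlignParams()
    cache: dict = {}
    return {name: align_assemblies(base, alts[name], p, _minimizer_cache=cache)
            for name in sorted(alts)}


# ---------------------------------------------------------------------------
# PAF and dot-plot I/O
# ---------------------------------------------------------------------------

def read_paf(path, min_mapq: int = 0, alt_assembly_name: str = "alt") -> list[AlignmentBlock]:
    """Read 12-column PAF; query = alternate, target = base.

    Records with mapping quality below ``min_mapq`` are skipped.  PAF
    blocks carry no anchors; reconciliation treats their endpoints as the
    anchor points.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 PAF columns, got {len(f)}")
            try:
                qlen, qs, qe = int(f[1]), int(f[2]), int(f[3])
                tlen, ts, te = int(f[6]), int(f[7]), int(f[8])
                nmatch, alen, mapq = int(f[9]), int(f[10]), int(f[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if f[4] not in "+-":
                raise ValueError(f"{path}: line {lineno}: bad strand {f[4]!r}")
            if mapq < min_mapq:
                continue
            blocks.append(AlignmentBlock(
                base_id=f[5], base_start=ts, base_end=te,
                alt_assembly_name=alt_assembly_name, alt_id=f[0],
                alt_start=qs, alt_end=qe, strand=f[4],
                n_anchors=0, score=nmatch, base_len=tlen, alt_len=qlen,
                mapq=mapq, aln_len=alen))
    return blocks


def write_paf(blocks: list[AlignmentBlock], path) -> None:
    with open(path, "w") as fh:
        for blk in blocks:
            fh.write("\t".join(map(str, [
                blk.alt_id, blk.alt_len, blk.alt_start, blk.alt_end, blk.strand,
                blk.base_id, blk.base_len, blk.base_start, blk.base_end,
                blk.score, blk.aln_len or blk.base_span, blk.mapq])) + "\n")


def write_dotplot_tsv(blocks: list[AlignmentBlock], path) -> None:
    """One row per block: the data behind a base-vs-alternate dot plot."""
    with open(path, "w") as fh:
        fh.write("base_id\tbase_start\tbase_end\talt_id\talt_start\talt_end\tstrand\n")
        for blk in blocks:
            fh.write(f"{blk.base_id}\t{blk.base_start}\t{blk.base_end}\t"
                     f"{blk.alt_id}\t{blk.alt_start}\t{blk.alt_end}\t{blk.strand}\n")
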