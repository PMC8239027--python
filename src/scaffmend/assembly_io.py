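"""Assembly I/O, gap location, contiguity statistics and AGP provenance.

An assembly is held in memory as an :class:`AssemblySet` — an ordered, named
collection of scaffolds whose sequences are uppercase strings over the DNA
alphabet (with ``N`` marking gap tracts).  All internal coordinates are
0-based half-open; AGP output converts to the standard's 1-based inclusive
convention.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

_GAP_RE = re.compile(r"N+")
_IUPAC_AMBIG = set("RYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Scaffold:
    """One assembled sequence, possibly containing N-gap tracts."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GapTract:
    """A maximal run of N characters on one scaffold (0-based half-open)."""

    scaffold_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Provenance components.  Each scaffold of an (edited) assembly is described
# as an ordered list of components: sequence stretches copied from a named
# source assembly, or runs of N introduced by an edit (e.g. a merge join).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqComponent:
    """A stretch of scaffold sequence copied from ``assembly:seq_id[start:end]``
    (reverse-complemented when strand is '-')."""

    assembly: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    def cut(self, offset: int) -> tuple["SeqComponent", "SeqComponent"]:
        """Split at ``offset`` bp from the component's left edge in scaffold
        orientation; strand-aware on the source coordinates."""
        if not 0 <= offset <= self.length:
            raise ValueError(f"cut offset {offset} outside component")
        if self.strand == "+":
            left = SeqComponent(self.assembly, self.seq_id, self.start, self.start + offset, "+")
            right = SeqComponent(self.assembly, self.seq_id, self.start + offset, self.end, "+")
        else:
            left = SeqComponent(self.assembly, self.seq_id, self.end - offset, self.end, "-")
            right = SeqComponent(self.assembly, self.seq_id, self.start, self.end - offset, "-")
        return left, right


@dataclass(frozen=True)
class GapComponent:
    """A run of N introduced by an edit (AGP gap row)."""

    length: int

    def cut(self, offset: int) -> tuple["GapComponent", "GapComponent"]:
        if not 0 <= offset <= self.length:
            raise ValueError(f"cut offset {offset} outside component")
        return GapComponent(offset), GapComponent(self.length - offset)


Component = SeqComponent | GapComponent


class AssemblySet:
    """Ordered, uniquely named collection of scaffolds.

    Optionally carries per-scaffold provenance (component lists) describing
    how each scaffold is composed from source assemblies; reconciliation
    edits keep the provenance in sync with the sequence.
    """

    def __init__(self, name: str = "assembly", scaffolds: Iterable[Scaffold] = ()):
        self.name = name
        self._scaffolds: dict[str, Scaffold] = {}
        self.provenance: dict[str, list[Component]] = {}
        for s in scaffolds:
            self.add(s)

    # -- container protocol -------------------------------------------------
    def add(self, scaffold: Scaffold, components: list[Component] | None = None) -> None:
        if scaffold.id in self._scaffolds:
            raise ValueError(f"duplicate scaffold id: {scaffold.id!r}")
        self._scaffolds[scaffold.id] = scaffold
        if components is None:
            components = [SeqComponent(self.name, scaffold.id, 0, scaffold.length, "+")]
        self.provenance[scaffold.id] = components

    def remove(self, scaffold_id: str) -> None:
        del self._scaffolds[scaffold_id]
        del self.provenance[scaffold_id]

    def __getitem__(self, scaffold_id: str) -> Scaffold:
        return self._scaffolds[scaffold_id]

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._scaffolds

    def __iter__(self) -> Iterator[Scaffold]:
        return iter(self._scaffolds.values())

    def __len__(self) -> int:
        return len(self._scaffolds)

    @property
    def ids(self) -> list[str]:
        return list(self._scaffolds)

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self)

    def lengths(self) -> dict[str, int]:
        return {s.id: s.length for s in self}

    def copy(self, name: str | None = None) -> "AssemblySet":
        out = AssemblySet(name or self.name)
        for s in self:
            out.add(Scaffold(s.id, s.sequence), list(self.provenance[s.id]))
        return out


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_assembly(path, name: str | None = None) -> AssemblySet:
    """Read a (optionally gzipped) FASTA file into an :class:`AssemblySet`.

    Sequences are uppercased and U is normalized to T.  IUPAC ambiguity
    codes other than N are preserved but reported in a warning.  Duplicate
    record IDs and empty files are errors.
    """
    if name is None:
        base = str(path).rsplit("/", 1)[-1]
        name = re.sub(r"\.(fa|fasta|fna)(\.gz)?$", "", base)
    asm = AssemblySet(name)
    ambig_ids: list[str] = []
    rec_id: str | None = None
    chunks: list[str] = []

    def _flush():
        nonlocal rec_id, chunks
        if rec_id is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for record {rec_id!r}")
        if _IUPAC_AMBIG & set(seq):
            ambig_ids.append(rec_id)
        if rec_id in asm:
            raise ValueError(f"duplicate record id in {path}: {rec_id!r}")
        asm.add(Scaffold(rec_id, seq))
        rec_id, chunks = None, []

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                rec_id = line[1:].split()[0]
                chunks = []
            else:
                if rec_id is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
        _flush()
    if len(asm) == 0:
        raise ValueError(f"{path}: no FASTA records found")
    if ambig_ids:
        log.warning(
            "%s: IUPAC ambiguity codes (non-N) present in %d record(s): %s",
            path, len(ambig_ids), ", ".join(ambig_ids[:5]),
        )
    return asm


def write_assembly(assembly: AssemblySet, path, width: int = 60) -> None:
    """Write FASTA with ``width``-column wrapping."""
    with _open_text(path, "wt") as fh:
        for s in assembly:
            fh.write(f">{s.id}\n")
            for i in range(0, s.length, width):
                fh.write(s.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gaps and contigs
# ---------------------------------------------------------------------------

def find_gaps(assembly: AssemblySet, min_gap_len: int = 1) -> list[GapTract]:
    """Every maximal N-run of length >= ``min_gap_len``, sorted by scaffold
    (input order) then start."""
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    gaps: list[GapTract] = []
    for s in assembly:
        for m in _GAP_RE.finditer(s.sequence):
            if m.end() - m.start() >= min_gap_len:
                gaps.append(GapTract(s.id, m.start(), m.end()))
    return gaps


def split_into_contigs(assembly: AssemblySet, min_split_gap: int = 1) -> AssemblySet:
    """Cut each scaffold at every N-run of length >= ``min_split_gap``.

    Contigs are named ``scaffoldID.1``, ``scaffoldID.2``, ... left to right;
    zero-length pieces are dropped (an all-N scaffold yields no contigs).
    """
    if min_split_gap < 1:
        raise ValueError("min_split_gap must be >= 1")
    out = AssemblySet(f"{assembly.name}.contigs")
    for s in assembly:
        cuts = [m.span() for m in _GAP_RE.finditer(s.sequence)
                if m.end() - m.start() >= min_split_gap]
        pos, n = 0, 0
        pieces: list[str] = []
        for gs, ge in cuts:
            pieces.append(s.sequence[pos:gs])
            pos = ge
        pieces.append(s.sequence[pos:])
        for piece in pieces:
            if not piece:
                continue
            n += 1
            out.add(Scaffold(f"{s.id}.{n}", piece))
        if n == 0:
            log.warning("scaffold %s is all N; no contigs emitted", s.id)
    return out


# ---------------------------------------------------------------------------
# Contiguity statistics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    n_sequences: int
    total_length: int
    max_length: int
    n50: int
    nx_curve: list[tuple[int, int]]  # (X percent, length bp), X = 1..100
    n_gaps: int
    gap_total_length: int
    n_over_10mb: int
    fraction_over_10mb: float
    contig_n50: int

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_sequences", "total_length", "max_length", "n50", "n_gaps",
            "gap_total_length", "n_over_10mb", "fraction_over_10mb", "contig_n50")}
        d["nx_curve"] = [list(p) for p in self.nx_curve]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.to_dict().items():
                if k == "nx_curve":
                    continue
                fh.write(f"{k}\t{v}\n")


def nx_curve(lengths: Sequence[int], xs: Iterable[int] = range(1, 101)) -> list[tuple[int, int]]:
    """NX values for the given length multiset.

    NX is the length of the shortest sequence in the minimal set of longest
    sequences covering X% of the total length; a sequence whose cumulative
    sum lands exactly on the X% boundary is included (ceiling convention).
    """
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    curve: list[tuple[int, int]] = []
    cum, i = 0, 0
    for x in xs:
        thresh = x * total / 100.0
        while cum < thresh:
            cum += srt[i]
            i += 1
        curve.append((x, srt[i - 1] if i else srt[0]))
    return curve


def write_nx_tsv(curve: list[tuple[int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("X\tlength_bp\n")
        for x, l in curve:
            fh.write(f"{x}\t{l}\n")


def compute_stats(assembly: AssemblySet, min_gap_len: int = 1) -> AssemblyStats:
    """Scaffold/contig contiguity statistics (N50, NX curve, gap counts)."""
    if len(assembly) == 0:
        raise ValueError("cannot compute statistics of an empty assembly")
    lengths = [s.length for s in assembly]
    total = sum(lengths)
    curve = nx_curve(lengths)
    gaps = find_gaps(assembly, min_gap_len)
    contigs = split_into_contigs(assembly, min_split_gap=min_gap_len)
    clen = [c.length for c in contigs]
    over = [l for l in lengths if l > 10_000_000]
    return AssemblyStats(
        n_sequences=len(lengths),
        total_length=total,
        max_length=max(lengths),
        n50=dict(curve)[50],
        nx_curve=curve,
        n_gaps=len(gaps),
        gap_total_length=sum(g.length for g in gaps),
        n_over_10mb=len(over),
        fraction_over_10mb=100.0 * sum(over) / total,
        contig_n50=dict(nx_curve(clen))[50] if clen else 0,
    )


# ---------------------------------------------------------------------------
# AGP output
# ---------------------------------------------------------------------------

def write_agp(assembly: AssemblySet, path, edits=None) -> None:
    """Write AGP v2.1 describing each scaffold as ordered components.

    Sequence components become W rows referencing their source assembly as
    ``<assembly>:<seq_id>`` (1-based inclusive source coordinates, with
    orientation); edit-introduced N runs become gap rows of gap_type
    ``scaffold`` with linkage evidence ``align_genus``.  ``edits`` is
    accepted for interface symmetry and only validated, the provenance
    carried on ``assembly`` is authoritative.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for s in assembly:
            comps = assembly.provenance[s.id]
            span = sum(c.length for c in comps)
            if span != s.length:
                raise ValueError(
                    f"provenance components of {s.id} span {span} bp "
                    f"but scaffold is {s.length} bp (overlapping or missing components)")
            pos, part = 0, 0
            for c in comps:
                if c.length == 0:
                    continue
                part += 1
                beg, end = pos + 1, pos + c.length
                if isinstance(c, SeqComponent):
                    fh.write("\t".join([
                        s.id, str(beg), str(end), str(part), "W",
                        f"{c.assembly}:{c.seq_id}", str(c.start + 1), str(c.end),
                        c.strand]) + "\n")
                else:
                    fh.write("\t".join([
                        s.id, str(beg), str(end), str(part), "N",
                        str(c.length), "scaffold", "yes", "align_genus"]) + "\n")
                pos += c.length


def render_components(components: list[Component],
                      sources: dict[str, AssemblySet]) -> str:
    """Reconstruct a scaffold's sequence from its provenance components and
    the named source assemblies (used to verify conservation)."""
    parts: list[str] = []
    for c in components:
        if isinstance(c, GapComponent):
            parts.append("N" * c.length)
        else:
            seq = sources[c.assembly][c.seq_id].sequence[c.start:c.end]
            parts.append(reverse_complement(seq) if c.strand == "-" else seq)
    return "".join(parts)
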