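"""Inversion calling from pairwise whole-genome alignment coordinate blocks.

A simple inversion appears in a target-vs-query alignment as a run of
reverse-orientation collinear blocks flanked by forward blocks. Calls are made
by chaining minus-strand blocks along the target: consecutive blocks whose
target-side gap is at most ``max_gap`` belong to one call. Short reverse
blocks (typically spurious repeat alignments) are filtered by ``min_block``
before chaining. Breakpoints are reported as the outer edges of the chained
target interval; on real assemblies they carry the uncertainty of the
flanking block edges, so `compare_breakpoints` takes a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from pathlib import Path
from typing import Iterable, Sequence

DEFAULT_MIN_BLOCK = 10_000
DEFAULT_MAX_GAP = 100_000


@dataclass(frozen=True)
class AlignmentBlock:
    """One collinear aligned segment; coordinates 0-based half-open, start < end."""

    target_chrom: str
    target_start: int
    target_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.target_start >= self.target_end:
            raise ValueError("target interval must satisfy start < end")
        if self.query_start >= self.query_end:
            raise ValueError("query interval must satisfy start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start


@dataclass
class InversionCall:
    """A chained run of minus-strand blocks, interpreted as one inversion."""

    target_chrom: str
    target_start: int
    target_end: int
    query_chrom: str
    query_start: int
    query_end: int
    n_blocks: int

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def length_delta(self) -> int:
        return self.query_span - self.target_span


def _norm(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


def read_blocks(path: str | Path, dialect: str = "show-coords-TH") -> list[AlignmentBlock]:
    """Read alignment blocks from ``show-coords -T -H``, PAF or the block TSV.

    show-coords encodes reverse alignments by descending query coordinates and
    uses 1-based inclusive coordinates; blocks are normalised to 0-based
    half-open with start < end plus an explicit strand. Normalising an already
    normalised row is a no-op (idempotent).
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                if dialect == "show-coords-TH":
                    # S1 E1 S2 E2 ... RefName QryName (1-based inclusive)
                    s1, e1, s2, e2 = (int(x) for x in fields[:4])
                    tname, qname = fields[-2], fields[-1]
                    strand = "+" if s2 <= e2 else "-"
                    ts, te = _norm(s1 - 1, e1)  # to 0-based half-open
                    qlo, qhi = _norm(s2, e2)
                    qs, qe = qlo - 1, qhi
                elif dialect == "paf":
                    qname = fields[0]
                    qs, qe = int(fields[2]), int(fields[3])
                    strand = fields[4]
                    tname = fields[5]
                    ts, te = int(fields[7]), int(fields[8])
                elif dialect == "tsv":
                    if fields[0] == "target_start":
                        continue  # header
                    ts, te, qs, qe = (int(x) for x in fields[:4])
                    strand, tname, qname = fields[4], fields[5], fields[6]
                    ts, te = _norm(ts, te)
                    qs, qe = _norm(qs, qe)
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except (ValueError, IndexError) as exc:
                if "unknown dialect" in str(exc):
                    raise
                raise ValueError(f"{path}: malformed row at line {lineno}") from exc
            blocks.append(
                AlignmentBlock(tname, ts, te, qname, qs, qe, strand)
            )
    return blocks


def call_inversions(
    blocks: Iterable[AlignmentBlock],
    min_block: int = DEFAULT_MIN_BLOCK,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[InversionCall]:
    """Chain minus-strand blocks into inversion calls.

    Blocks shorter than ``min_block`` on the target are ignored. Surviving
    minus blocks are grouped by (target_chrom, query_chrom), sorted by
    target_start, and chained while the target gap between consecutive blocks
    is at most ``max_gap``. Output order and content are independent of input
    block order.
    """
    minus = sorted(
        (
            b
            for b in blocks
            if b.strand == "-" and b.target_length >= min_block
        ),
        key=lambda b: (b.target_chrom, b.query_chrom, b.target_start, b.target_end),
    )
    calls: list[InversionCall] = []
    for (tchrom, qchrom), group in groupby(
        minus, key=lambda b: (b.target_chrom, b.query_chrom)
    ):
        chain: list[AlignmentBlock] = []
        chain_end = 0  # running max target end: nested blocks must not shrink it
        for block in group:
            if chain and block.target_start - chain_end > max_gap:
                calls.append(_emit(tchrom, qchrom, chain))
                chain = []
            chain.append(block)
            chain_end = max(chain_end, block.target_end) if len(chain) > 1 else block.target_end
        if chain:
            calls.append(_emit(tchrom, qchrom, chain))
    return calls


def _emit(tchrom: str, qchrom: str, chain: Sequence[AlignmentBlock]) -> InversionCall:
    return InversionCall(
        target_chrom=tchrom,
        target_start=min(b.target_start for b in chain),
        target_end=max(b.target_end for b in chain),
        query_chrom=qchrom,
        query_start=min(b.query_start for b in chain),
        query_end=max(b.query_end for b in chain),
        n_blocks=len(chain),
    )


def length_delta(call: InversionCall) -> int:
    """Query span minus target span; positive means the query haplotype expanded."""
    return call.length_delta


def compare_breakpoints(
    call_a: InversionCall, call_b: InversionCall, tolerance: int
) -> tuple[bool, tuple[int, int]]:
    """Do two calls on a shared target share breakpoints within ``tolerance`` bp?

    Returns (shared, (start_offset, end_offset)); offsets are b minus a.
    """
    off_start = call_b.target_start - call_a.target_start
    off_end = call_b.target_end - call_a.target_end
    shared = (
        call_a.target_chrom == call_b.target_chrom
        and abs(off_start) <= tolerance
        and abs(off_end) <= tolerance
    )
    return shared, (off_start, off_end)


def write_calls_tsv(path: str | Path, calls: Sequence[InversionCall]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "target_chrom\ttarget_start\ttarget_end\tquery_chrom\tquery_start"
            "\tquery_end\tn_blocks\ttarget_span\tquery_span\tlength_delta\n"
        )
        for c in calls:
            fh.write(
                f"{c.target_chrom}\t{c.target_start}\t{c.target_end}"
                f"\t{c.query_chrom}\t{c.query_start}\t{c.query_end}"
                f"\t{c.n_blocks}\t{c.target_span}\t{c.query_span}\t{c.length_delta}\n"
            )
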