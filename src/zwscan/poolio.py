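"""Readers/writers for the pipeline's tabular formats and coordinate conventions.

Coordinate conventions
----------------------
Everything in memory is 0-based half-open. The two upstream text formats that
are not follow their own conventions at the I/O boundary only:

* sync (Popoolation2 dialect): positions are 1-based; per-pool counts are
  ``A:T:C:G:N:del``. ``N`` and ``del`` are parsed but excluded from depth and
  frequency — the scan concerns nucleotide SNPs only.
* BED: 0-based half-open, as usual.

A site at 1-based position ``p`` belongs to the window containing ``p - 1``,
matching bedtools semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
#: column order of a sync count field
SYNC_ORDER = ("A", "T", "C", "G", "N", "del")

#: pools shallower than this are uninformative for a 0.9 fixation cutoff
DEFAULT_MIN_DEPTH = 4


class SyncParseError(ValueError):
    """Malformed sync input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class PooledSiteCounts:
    """Per-site A/C/G/T read counts for two sequencing pools.

    ``pos`` is 1-based (sync convention). Count maps may omit zero alleles;
    ``N``/``del`` tokens never appear in them.
    """

    chrom: str
    pos: int
    ref: str
    counts_pool1: dict[str, int]
    counts_pool2: dict[str, int]

    def depth(self, pool: int) -> int:
        counts = self.counts_pool1 if pool == 1 else self.counts_pool2
        return sum(counts.get(n, 0) for n in NUCLEOTIDES)


@dataclass
class GenomicWindow:
    """Half-open genomic interval carrying one statistic (density, fraction...)."""

    chrom: str
    start: int
    end: int
    value: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SyncReport:
    """Bookkeeping from a sync read: nothing is dropped silently."""

    n_sites: int = 0
    n_dropped_low_depth: int = 0
    dropped_positions: list[tuple[str, int]] = field(default_factory=list)


def _parse_count_field(token: str, lineno: int) -> dict[str, int]:
    parts = token.split(":")
    if len(parts) != len(SYNC_ORDER):
        raise SyncParseError(
            lineno, f"count field {token!r} has {len(parts)} values, expected 6"
        )
    try:
        values = [int(p) for p in parts]
    except ValueError as exc:
        raise SyncParseError(lineno, f"non-integer count in {token!r}") from exc
    if any(v < 0 for v in values):
        raise SyncParseError(lineno, f"negative count in {token!r}")
    return {n: v for n, v in zip(SYNC_ORDER, values) if n in NUCLEOTIDES and v > 0}


def iter_sync(
    path: str | Path,
    min_depth: int = DEFAULT_MIN_DEPTH,
    report: SyncReport | None = None,
) -> Iterator[PooledSiteCounts]:
    """Stream sites from a sync file, dropping (and counting) shallow ones.

    A site is dropped when *either* pool's nucleotide depth is below
    ``min_depth``. Malformed lines raise :class:`SyncParseError` naming the
    line; dropped sites are tallied in ``report`` and logged at the end.
    """
    own_report = report if report is not None else SyncReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise SyncParseError(
                    lineno, f"expected >=5 tab-separated columns, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SyncParseError(lineno, f"bad position {pos_s!r}") from exc
            if pos < 1:
                raise SyncParseError(lineno, f"position {pos} < 1")
            if ref.upper() not in NUCLEOTIDES + ("N",):
                raise SyncParseError(lineno, f"unknown reference base {ref!r}")
            site = PooledSiteCounts(
                chrom=chrom,
                pos=pos,
                ref=ref.upper(),
                counts_pool1=_parse_count_field(fields[3], lineno),
                counts_pool2=_parse_count_field(fields[4], lineno),
            )
            if site.depth(1) < min_depth or site.depth(2) < min_depth:
                own_report.n_dropped_low_depth += 1
                own_report.dropped_positions.append((chrom, pos))
                continue
            own_report.n_sites += 1
            yield site
    logger.info(
        "sync read: %d sites kept, %d dropped below depth %d",
        own_report.n_sites,
        own_report.n_dropped_low_depth,
        min_depth,
    )


def read_sync(
    path: str | Path, min_depth: int = DEFAULT_MIN_DEPTH
) -> tuple[list[PooledSiteCounts], SyncReport]:
    """Read a whole sync file; returns (sites, report)."""
    report = SyncReport()
    sites = list(iter_sync(path, min_depth=min_depth, report=report))
    return sites, report


def write_sync(path: str | Path, sites: Iterable[PooledSiteCounts]) -> None:
    with open(path, "w") as fh:
        for site in sites:
            cols = [site.chrom, str(site.pos), site.ref]
            for counts in (site.counts_pool1, site.counts_pool2):
                cols.append(":".join(str(counts.get(n, 0)) for n in SYNC_ORDER))
            fh.write("\t".join(cols) + "\n")


def make_windows(
    chrom_length: int, window_size: int, chrom: str = "chr"
) -> list[GenomicWindow]:
    """Tile ``[0, chrom_length)`` with ``window_size`` windows, truncating the last.

    No empty trailing window is emitted when the length is an exact multiple.
    """
    if chrom_length <= 0:
        raise ValueError(f"chrom_length must be positive, got {chrom_length}")
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    return [
        GenomicWindow(chrom, start, min(start + window_size, chrom_length))
        for start in range(0, chrom_length, window_size)
    ]


def window_index(pos_1based: int, window_size: int) -> int:
    """Index of the tiling window holding a 1-based site position."""
    return (pos_1based - 1) // window_size


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based half-open)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


def write_bed(
    path: str | Path, intervals: Iterable[tuple[str, int, int]]
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_windows_tsv(path: str | Path, windows: Sequence[GenomicWindow]) -> None:
    """``chrom start end value`` per window; missing values written as NA."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tvalue\n")
        for w in windows:
            value = "NA" if w.value is None else repr(w.value)
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{value}\n")
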