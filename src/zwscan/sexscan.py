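"""Sex-patterned SNP classification, windowed densities and region calling.

A sex-linked SNP in pooled data is fixed in one sex and polymorphic in the
other. With female heterogamety (ZW) the W-linked allele is expected at
frequency 0.5 in the female pool and absent from males; the mirrored pattern
(polymorphic in males, fixed in females) indicates XY. To tolerate sequencing
error and finite-pool sampling, fixation is declared when the major allele of
the fixed sex exceeds 0.9, and "polymorphic" means the diagnostic allele lies
strictly between 0.3 and 0.7 in the other sex. All cutoffs are strict
inequalities.

Pool 1 is the male pool and pool 2 the female pool throughout; swapping the
two pools maps every ZW call to an XY call and vice versa, exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .fst import SiteFrequencies
from .poolio import GenomicWindow, window_index

logger = logging.getLogger(__name__)

FIX_CUTOFF = 0.9
POLY_LOW = 0.3
POLY_HIGH = 0.7
#: windows of elevated density needed to open a region call
DEFAULT_MIN_RUN_WINDOWS = 10
#: below-threshold windows tolerated inside a run, sized to bridge the
#: ~600-800 kb TE-dense dropouts seen inside inverted sex regions
DEFAULT_GAP_WINDOWS = 8
#: ZW SNPs per 100 kb window needed to count a window as elevated
DEFAULT_MIN_DENSITY = 5.0


@dataclass
class SexPatternCall:
    """Classification of one site as XY-, ZW-patterned or neither."""

    chrom: str
    pos: int
    pattern: str  # 'XY', 'ZW' or 'none'
    diagnostic_allele: str | None
    freq_in_male_pool: float | None
    freq_in_female_pool: float | None


@dataclass
class SexRegionCall:
    """A window-aligned candidate sex-determining region."""

    chrom: str
    start: int
    end: int
    n_support_windows: int
    mean_density: float
    flank_density: float


def _fixed_against(freqs: dict[str, float], allele: str, cutoff: float) -> bool:
    """Is some allele other than `allele` above the fixation cutoff?"""
    return any(f > cutoff for a, f in freqs.items() if a != allele)


def classify_site(
    freqs: SiteFrequencies,
    fix_cutoff: float = FIX_CUTOFF,
    poly_low: float = POLY_LOW,
    poly_high: float = POLY_HIGH,
) -> SexPatternCall:
    """Classify one site; pool 1 = males, pool 2 = females.

    ZW: a diagnostic allele polymorphic in females (strictly inside
    (poly_low, poly_high)) while the male pool's complementary major allele
    exceeds fix_cutoff. XY is the sex-mirrored rule. With fix_cutoff >
    poly_high the two patterns are mutually exclusive; a simultaneous match
    (possible only with looser cutoffs) yields 'none' with a warning.
    """
    fm, ff = freqs.freq_pool1, freqs.freq_pool2

    zw_candidates = [
        a
        for a in freqs.alleles
        if poly_low < ff.get(a, 0.0) < poly_high and _fixed_against(fm, a, fix_cutoff)
    ]
    xy_candidates = [
        a
        for a in freqs.alleles
        if poly_low < fm.get(a, 0.0) < poly_high and _fixed_against(ff, a, fix_cutoff)
    ]

    if zw_candidates and xy_candidates:
        logger.warning(
            "%s:%d matches both ZW and XY under the supplied cutoffs; "
            "reporting 'none'",
            freqs.chrom,
            freqs.pos,
        )
        pattern, allele = "none", None
    elif zw_candidates:
        pattern = "ZW"
        allele = max(zw_candidates, key=lambda a: (ff.get(a, 0.0), a))
    elif xy_candidates:
        pattern = "XY"
        allele = max(xy_candidates, key=lambda a: (fm.get(a, 0.0), a))
    else:
        pattern, allele = "none", None

    return SexPatternCall(
        chrom=freqs.chrom,
        pos=freqs.pos,
        pattern=pattern,
        diagnostic_allele=allele,
        freq_in_male_pool=fm.get(allele) if allele else None,
        freq_in_female_pool=ff.get(allele) if allele else None,
    )


def pattern_density(
    calls: Iterable[SexPatternCall],
    windows: Sequence[GenomicWindow],
    pattern: str,
    per_kb: bool = False,
) -> list[GenomicWindow]:
    """Per-window count of sites carrying `pattern` (optionally per kb).

    Windows must tile one chromosome; a site at 1-based position p falls in
    the window containing p - 1.
    """
    if not windows:
        return []
    window_size = windows[0].end - windows[0].start
    counts = [0] * len(windows)
    for call in calls:
        if call.pattern != pattern or call.chrom != windows[0].chrom:
            continue
        i = window_index(call.pos, window_size)
        if 0 <= i < len(windows):
            counts[i] += 1
    out = []
    for w, c in zip(windows, counts):
        value = c / (w.length / 1000.0) if per_kb else float(c)
        out.append(GenomicWindow(w.chrom, w.start, w.end, value))
    return out


def call_sex_region(
    densities: Sequence[GenomicWindow],
    min_density: float = DEFAULT_MIN_DENSITY,
    min_run_windows: int = DEFAULT_MIN_RUN_WINDOWS,
    gap_windows: int = DEFAULT_GAP_WINDOWS,
) -> list[SexRegionCall]:
    """Call candidate sex regions from a tiling of pattern densities.

    A region is a maximal run of windows with density >= min_density,
    allowing up to gap_windows consecutive below-threshold windows inside the
    run (TE-dense stretches suppress SNP calling and punch holes in otherwise
    contiguous regions). Runs supported by fewer than min_run_windows elevated
    windows are discarded. Returned intervals are aligned to window
    boundaries, from the first to the last elevated window.
    """
    above = [w.value >= min_density for w in densities]
    runs: list[tuple[int, int]] = []  # [first, last] elevated window indices
    start: int | None = None
    last_above: int | None = None
    for i, hit in enumerate(above):
        if hit:
            if start is None:
                start = i
            elif last_above is not None and i - last_above - 1 > gap_windows:
                runs.append((start, last_above))
                start = i
            last_above = i
    if start is not None and last_above is not None:
        runs.append((start, last_above))

    calls: list[SexRegionCall] = []
    in_any_run: set[int] = set()
    kept_runs = []
    for lo, hi in runs:
        n_support = sum(above[lo : hi + 1])
        if n_support >= min_run_windows:
            kept_runs.append((lo, hi, n_support))
            in_any_run.update(range(lo, hi + 1))
    flank_values = [
        w.value for i, w in enumerate(densities) if i not in in_any_run
    ]
    flank = sum(flank_values) / len(flank_values) if flank_values else 0.0
    for lo, hi, n_support in kept_runs:
        members = densities[lo : hi + 1]
        calls.append(
            SexRegionCall(
                chrom=members[0].chrom,
                start=members[0].start,
                end=members[-1].end,
                n_support_windows=n_support,
                mean_density=sum(w.value for w in members) / len(members),
                flank_density=flank,
            )
        )
    return calls
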