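"""Transposable-element landscape: windowed base fractions, inside/outside
inversion comparison and peak detection.

The TE burden of a chromosome is summarised as the fraction of bases covered
by (merged) TE annotation intervals per tiling window — 200 kb by default.
Windows are then partitioned relative to a supplied inversion interval and
the inside-vs-outside means compared with a one-tailed two-sample t-test
(Welch by default; Student's available by flag) under the alternative that
the inversion is TE-enriched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .poolio import GenomicWindow

Interval = tuple[int, int]

DEFAULT_WINDOW_SIZE = 200_000

LABEL_INSIDE = "inside_inversion"
LABEL_OUTSIDE = "outside_inversion_same_chrom"
LABEL_REST = "rest_of_genome"


@dataclass
class TeTestResult:
    statistic: float
    pvalue: float
    mean_inside: float
    mean_outside: float
    n_inside: int
    n_outside: int


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping or touching half-open intervals; output sorted."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"empty or inverted interval ({start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def te_fraction(
    windows: Sequence[GenomicWindow],
    te_intervals: Sequence[Interval],
    inversion: Interval | None = None,
    chrom: str | None = None,
) -> pd.DataFrame:
    """Per-window TE base fraction; overlapping annotations merged first.

    Columns: chrom, start, end, fraction, label. Labels split windows by
    midpoint position relative to ``inversion`` (windows on other chromosomes
    get the rest_of_genome label). Conservation holds exactly: the sum of
    fraction x window length over a tiling equals the merged TE bp.
    """
    merged = merge_intervals(te_intervals) if te_intervals else []
    rows = []
    for w in windows:
        covered = sum(_overlap((w.start, w.end), te) for te in merged)
        if inversion is not None and (chrom is None or w.chrom == chrom):
            mid = (w.start + w.end) // 2
            label = LABEL_INSIDE if inversion[0] <= mid < inversion[1] else LABEL_OUTSIDE
        else:
            label = LABEL_REST
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "fraction": covered / w.length,
                "label": label,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fraction", "label"])


def group_fractions(
    table: pd.DataFrame, window_size: int = DEFAULT_WINDOW_SIZE
) -> tuple[list[float], list[float]]:
    """Inside/outside fraction samples for the t-test.

    Truncated final windows shorter than half the window size keep their
    fraction in the table but are excluded here: grossly unequal window
    lengths distort the per-window variance the test assumes.
    """
    full = table[(table["end"] - table["start"]) >= window_size / 2]
    inside = full.loc[full["label"] == LABEL_INSIDE, "fraction"].tolist()
    outside = full.loc[full["label"] != LABEL_INSIDE, "fraction"].tolist()
    return inside, outside


def compare_te(
    inside: Sequence[float],
    outside: Sequence[float],
    alternative: str = "greater",
    equal_var: bool = False,
) -> TeTestResult:
    """One-tailed two-sample t-test of mean(inside) > mean(outside).

    Welch's unequal-variance form by default (equal_var=True gives
    Student's). Identical groups give t = 0 and one-tailed p = 0.5.
    """
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError("each group needs at least 2 windows")
    res = stats.ttest_ind(
        inside, outside, equal_var=equal_var, alternative=alternative
    )
    return TeTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_inside=float(sum(inside) / len(inside)),
        mean_outside=float(sum(outside) / len(outside)),
        n_inside=len(inside),
        n_outside=len(outside),
    )


def find_te_peaks(
    table: pd.DataFrame, peak_fraction: float, min_run: int = 1
) -> list[Interval]:
    """Maximal runs of >= min_run consecutive windows with fraction >= peak_fraction.

    ``table`` must be a tiling of one chromosome in coordinate order (it is
    re-sorted defensively, so input row order does not matter).
    """
    t = table.sort_values(["chrom", "start"]).reset_index(drop=True)
    peaks: list[Interval] = []
    run_start: int | None = None
    prev_end: int | None = None
    n_run = 0
    for row in t.itertuples(index=False):
        if row.fraction >= peak_fraction:
            if run_start is None:
                run_start, n_run = row.start, 0
            n_run += 1
            prev_end = row.end
        else:
            if run_start is not None and n_run >= min_run:
                peaks.append((run_start, prev_end))
            run_start = None
    if run_start is not None and n_run >= min_run:
        peaks.append((run_start, prev_end))
    return peaks
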