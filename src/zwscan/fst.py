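"""Per-site pooled allele frequencies and Nei's G_ST between the two sex pools.

At each variable site the differentiation between the male-read and
female-read pools is summarised by Nei's G_ST::

    H_S = mean over the two pools of (1 - sum_k p_k^2)
    H_T = 1 - sum_k p_bar_k^2,   p_bar_k = (p_k,pool1 + p_k,pool2) / 2
    G_ST = (H_T - H_S) / H_T

with the unweighted mean of pool frequencies for p_bar (the pools are
equal-sized by design). G_ST is 0 for identical pool frequencies, 1 for fixed
alternative alleles, and undefined — reported as missing, not 0 — when the
site is monomorphic overall (H_T = 0): "no variation" is not the same thing
as "no differentiation". The formula sums over however many alleles are
observed, so multi-allelic sites need no special casing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .poolio import NUCLEOTIDES, PooledSiteCounts, make_windows

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 100_000


@dataclass
class SiteFrequencies:
    """Observed allele frequencies of one site in each pool."""

    chrom: str
    pos: int
    alleles: tuple[str, ...]
    freq_pool1: dict[str, float]
    freq_pool2: dict[str, float]
    depth_pool1: int
    depth_pool2: int


def site_frequencies(site: PooledSiteCounts) -> SiteFrequencies | None:
    """Count-based frequencies per pool; alleles absent from both pools omitted.

    Returns None (with a logged reason) if either pool has zero depth.
    """
    d1, d2 = site.depth(1), site.depth(2)
    if d1 == 0 or d2 == 0:
        logger.info("skipping %s:%d: zero depth in a pool", site.chrom, site.pos)
        return None
    alleles = tuple(
        n
        for n in NUCLEOTIDES
        if site.counts_pool1.get(n, 0) + site.counts_pool2.get(n, 0) > 0
    )
    return SiteFrequencies(
        chrom=site.chrom,
        pos=site.pos,
        alleles=alleles,
        freq_pool1={n: site.counts_pool1.get(n, 0) / d1 for n in alleles},
        freq_pool2={n: site.counts_pool2.get(n, 0) / d2 for n in alleles},
        depth_pool1=d1,
        depth_pool2=d2,
    )


def nei_gst(freqs: SiteFrequencies) -> float:
    """Nei's G_ST for one site; NaN when the site is monomorphic overall."""
    hs = 0.0
    for pool in (freqs.freq_pool1, freqs.freq_pool2):
        hs += 1.0 - sum(p * p for p in pool.values())
    hs /= 2.0
    ht = 1.0 - sum(
        ((freqs.freq_pool1.get(a, 0.0) + freqs.freq_pool2.get(a, 0.0)) / 2.0) ** 2
        for a in freqs.alleles
    )
    if ht <= 0.0:
        return math.nan
    return (ht - hs) / ht


def fst_scan(
    sites: Iterable[PooledSiteCounts],
    window_size: int = DEFAULT_WINDOW_SIZE,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site G_ST table plus per-window mean G_ST.

    ``sites`` must be sorted by (chrom, pos); unsorted input raises. Windows
    with no defined G_ST values carry a missing mean. Window tilings extend to
    ``chrom_lengths`` when given, otherwise to the last observed site.
    """
    rows: list[dict] = []
    last: tuple[str, int] | None = None
    for site in sites:
        key = (site.chrom, site.pos)
        if last is not None and site.chrom == last[0] and site.pos < last[1]:
            raise ValueError(
                f"input not sorted: {site.chrom}:{site.pos} after {last[0]}:{last[1]}"
            )
        last = key
        freqs = site_frequencies(site)
        if freqs is None:
            continue
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "gst": nei_gst(freqs),
                "depth1": freqs.depth_pool1,
                "depth2": freqs.depth_pool2,
            }
        )
    site_df = pd.DataFrame(rows, columns=["chrom", "pos", "gst", "depth1", "depth2"])

    window_rows: list[dict] = []
    for chrom, group in site_df.groupby("chrom", sort=True):
        length = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else int(group["pos"].max())
        )
        windows = make_windows(length, window_size, chrom=chrom)
        idx = (group["pos"] - 1) // window_size
        means = group.groupby(idx)["gst"].mean()
        counts = group.groupby(idx)["gst"].count()
        for i, w in enumerate(windows):
            window_rows.append(
                {
                    "chrom": chrom,
                    "start": w.start,
                    "end": w.end,
                    "mean_gst": means.get(i, math.nan),
                    "n_sites": int(counts.get(i, 0)),
                }
            )
    window_df = pd.DataFrame(
        window_rows, columns=["chrom", "start", "end", "mean_gst", "n_sites"]
    )
    return site_df, window_df
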