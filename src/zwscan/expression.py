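"""Sex-contrast expression summaries on FPKM tables and allele-specific ratios.

Fold changes are oriented female over male: log2_fold_change =
log2(female_fpkm / male_fpkm), so a gene expressed mainly in ovary is
positive and a testis-biased gene negative. An optional pseudocount epsilon
handles zero-FPKM genes; with the default epsilon = 0 a single zero yields a
signed infinity (direction preserved) and a double zero is missing.

Allele-specific expression at a heterozygous (ZW) locus is summarised as the
W-read fraction W / (W + Z) with a Wilson 95% score interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

DEFAULT_MIN_ABS_LFC = 2.0
DEFAULT_MIN_MAX_FPKM = 1.0


@dataclass
class AlleleRatio:
    w_reads: int
    z_reads: int
    w_fraction: float
    ci_low: float
    ci_high: float


def log2_fold_change(
    male_fpkm: float, female_fpkm: float, epsilon: float = 0.0
) -> float:
    """log2((female + eps) / (male + eps)); inf/-inf on single zeros, NaN on double."""
    if male_fpkm < 0 or female_fpkm < 0:
        raise ValueError("FPKM values must be non-negative")
    num, den = female_fpkm + epsilon, male_fpkm + epsilon
    if num == 0.0 and den == 0.0:
        return math.nan
    if den == 0.0:
        return math.inf
    if num == 0.0:
        return -math.inf
    return math.log2(num / den)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, location, male_fpkm, female_fpkm."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "male_fpkm", "female_fpkm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table lacks columns: {sorted(missing)}")
    return df


def add_fold_changes(table: pd.DataFrame, epsilon: float = 0.0) -> pd.DataFrame:
    out = table.copy()
    out["lfc"] = [
        log2_fold_change(m, f, epsilon)
        for m, f in zip(out["male_fpkm"], out["female_fpkm"])
    ]
    return out


def flag_de(
    table: pd.DataFrame,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
    min_max_fpkm: float = DEFAULT_MIN_MAX_FPKM,
) -> pd.DataFrame:
    """Mark records with |lfc| >= min_abs_lfc and max(male, female) >= min_max_fpkm.

    Expects an ``lfc`` column (see add_fold_changes); adds a boolean
    ``de_flag``. NaN fold changes never pass; infinite ones pass the lfc
    condition in their direction.
    """
    if "lfc" not in table.columns:
        raise ValueError("table has no 'lfc' column; call add_fold_changes first")
    out = table.copy()
    max_fpkm = out[["male_fpkm", "female_fpkm"]].max(axis=1)
    abs_lfc = out["lfc"].abs()
    out["de_flag"] = (abs_lfc >= min_abs_lfc) & (max_fpkm >= min_max_fpkm)
    out.loc[out["lfc"].isna(), "de_flag"] = False
    return out


def allele_ratio(w_reads: int, z_reads: int, alpha: float = 0.05) -> AlleleRatio:
    """W-read fraction with a Wilson score interval; total must be positive."""
    if w_reads < 0 or z_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = w_reads + z_reads
    if total == 0:
        raise ValueError("no reads: ratio undefined")
    low, high = proportion_confint(w_reads, total, alpha=alpha, method="wilson")
    return AlleleRatio(
        w_reads=w_reads,
        z_reads=z_reads,
        w_fraction=w_reads / total,
        ci_low=float(low),
        ci_high=float(high),
    )
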