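"""Microsatellite / marker diversity statistics.

Genotypes arrive as a long-format table (one row per individual x locus,
columns ``individual group locus allele1 allele2``, missing = "."). Alleles
are typically fragment sizes in bp but any hashable identifier works. Each
non-missing diploid genotype contributes two gene copies to its group x locus
frequency tally; no small-sample correction is applied.

Statistics:

* effective number of alleles N_e = 1 / sum_i p_i^2 — the allele count of an
  equifrequent locus with the same expected homozygosity; 1 for a
  monomorphic locus, k for k equifrequent alleles.
* private alleles — alleles present (above ``min_freq``) in exactly one group
  at a locus; with the default min_freq = 0 "absent" means never observed.
* allele frequency from genotype class proportions: with a dominant marker
  scored as heterozygote/homozygote proportions p_het and p_hom, the allele
  frequency is (p_het + 2 p_hom) / 2.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "."

GENOTYPE_COLUMNS = ["individual", "group", "locus", "allele1", "allele2"]


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Long-format genotype TSV; missing alleles coded '.'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"genotype table lacks columns: {sorted(missing_cols)}")
    return df


def allele_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Gene-copy allele frequencies per group x locus.

    Rows with a missing allele ('.' or NA) are excluded entirely (both copies).
    Output columns: group, locus, allele, count, n_copies, freq. Group x locus
    combinations with no scored genotypes are absent from the output (logged).
    """
    t = table.copy()
    t["allele1"] = t["allele1"].astype(str)
    t["allele2"] = t["allele2"].astype(str)
    scored = t[
        (t["allele1"] != MISSING)
        & (t["allele2"] != MISSING)
        & t["allele1"].notna()
        & t["allele2"].notna()
    ]
    n_dropped = len(t) - len(scored)
    if n_dropped:
        logger.info("allele_frequencies: %d genotypes with missing data excluded", n_dropped)
    if scored.empty:
        return pd.DataFrame(
            columns=["group", "locus", "allele", "count", "n_copies", "freq"]
        )
    long = pd.concat(
        [
            scored[["group", "locus", "allele1"]].rename(columns={"allele1": "allele"}),
            scored[["group", "locus", "allele2"]].rename(columns={"allele2": "allele"}),
        ]
    )
    counts = (
        long.groupby(["group", "locus", "allele"]).size().rename("count").reset_index()
    )
    counts["n_copies"] = counts.groupby(["group", "locus"])["count"].transform("sum")
    counts["freq"] = counts["count"] / counts["n_copies"]
    return counts.sort_values(["group", "locus", "allele"]).reset_index(drop=True)


def effective_allele_number(freqs: Sequence[float] | Mapping[Hashable, float]) -> float:
    """N_e = 1 / sum p_i^2; requires frequencies summing to 1."""
    values = list(freqs.values()) if isinstance(freqs, Mapping) else list(freqs)
    if not values:
        raise ValueError("empty frequency set")
    total = sum(values)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {total}, expected 1")
    return 1.0 / sum(p * p for p in values)


def effective_alleles_table(freq_table: pd.DataFrame) -> pd.DataFrame:
    """N_e per group x locus from an allele_frequencies() output table."""
    rows = []
    for (group, locus), sub in freq_table.groupby(["group", "locus"]):
        rows.append(
            {
                "group": group,
                "locus": locus,
                "n_alleles": len(sub),
                "n_copies": int(sub["n_copies"].iloc[0]),
                "effective_alleles": effective_allele_number(sub["freq"].tolist()),
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "locus", "n_alleles", "n_copies", "effective_alleles"]
    )


def private_alleles(
    freq_table: pd.DataFrame, min_freq: float = 0.0
) -> dict[tuple[str, str], dict[str, float]]:
    """Alleles private to one group at each locus.

    An allele is private to a group when its frequency there exceeds
    ``min_freq`` while being at most ``min_freq`` in every other group sharing
    the locus. Returns {(group, locus): {allele: freq}} for loci scored in
    at least two groups.
    """
    out: dict[tuple[str, str], dict[str, float]] = {}
    for locus, sub in freq_table.groupby("locus"):
        groups = sub["group"].unique()
        if len(groups) < 2:
            continue
        freq_by_group = {
            g: dict(zip(gsub["allele"], gsub["freq"]))
            for g, gsub in sub.groupby("group")
        }
        for g in groups:
            private = {
                allele: f
                for allele, f in freq_by_group[g].items()
                if f > min_freq
                and all(
                    freq_by_group[other].get(allele, 0.0) <= min_freq
                    for other in groups
                    if other != g
                )
            }
            if private:
                out[(g, locus)] = private
    return out


def allele_freq_from_genotypes(p_het: float, p_hom_alt: float) -> float:
    """Allele frequency implied by heterozygote / alt-homozygote proportions.

    Each heterozygote carries one copy of the allele and each homozygote two,
    so the frequency is (p_het + 2 p_hom_alt) / 2.
    """
    for name, p in (("p_het", p_het), ("p_hom_alt", p_hom_alt)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if p_het + p_hom_alt > 1.0 + 1e-12:
        raise ValueError("genotype proportions exceed 1")
    return (p_het + 2.0 * p_hom_alt) / 2.0
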