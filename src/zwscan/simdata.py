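"""Synthetic pooled-sequencing data with the structure the scan assumes.

The generator emulates the sampling design of a pooled resequencing study of a
female-heterogametic (ZW) cichlid population: two pools of 20 fish (one per
sex) sequenced to ~1x per individual, a sex-determining region in which
W-linked SNPs sit at population frequency 0.5 in females and 0 in males, an
inverted chromosome segment that shows up as reverse-orientation alignment
blocks (with an expanded query haplotype), and transposable-element intervals
that are denser inside designated peak regions of the inversion.

Sampling is two-stage: first the 2N gene copies of each pool are drawn from
the population frequency (finite-pool variance — the reason the classifier
tolerates 0.3-0.7 rather than demanding 0.5), then reads are drawn binomially
from the realised pool frequency at a Poisson depth. One global seed drives
everything; each operation derives its own independent substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .inversion import AlignmentBlock
from .poolio import NUCLEOTIDES, PooledSiteCounts

Interval = tuple[int, int]

# substream labels: one child seed per operation, derived from the global seed
_STREAMS = {"population": 0, "counts": 1, "te": 2, "blocks": 3}


def _default_te_peaks() -> list[Interval]:
    # three 400 kb high-TE segments inside the default inversion, mirroring
    # the repeat expansions observed inside the inverted haplotype
    inv_start, inv_end = 14_500_000, 21_390_000
    span = inv_end - inv_start
    peaks = []
    for f in (0.2, 0.5, 0.8):
        mid = inv_start + int(f * span)
        peaks.append((mid - 200_000, mid + 200_000))
    return peaks


@dataclass
class SimConfig:
    """Parameters of one synthetic chromosome and its two sex pools.

    Defaults reproduce the study design this package targets: a 31 Mb
    chromosome, an 8.6 Mb sex region at [14.5, 23.1) Mb containing a 6.89 Mb
    inversion, pools of 20 individuals at 1x each, TE base fraction 0.27 with
    three 400 kb peaks at 0.5 (~0.31 averaged over the inversion), and a
    1.3 Mb repeat expansion of the inverted query haplotype.
    """

    genome_length: int = 31_000_000
    sex_region: Interval | None = (14_500_000, 23_100_000)
    n_zw_sites: int = 860
    n_background_snps: int = 5_000
    pool_size: int = 20
    per_individual_coverage: float = 1.0
    te_base_rate: float = 0.27
    te_peak_rate: float = 0.5
    te_peak_intervals: list[Interval] = field(default_factory=_default_te_peaks)
    inversion_segment: Interval | None = (14_500_000, 21_390_000)
    query_expansion_bp: int = 1_300_000
    chrom: str = "chr5"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        for name in ("te_base_rate", "te_peak_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        for iv in [self.sex_region, self.inversion_segment, *self.te_peak_intervals]:
            if iv is None:
                continue
            s, e = iv
            if not (0 <= s < e <= self.genome_length):
                raise ValueError(f"interval {iv} outside [0, {self.genome_length})")
        if self.sex_region is None and self.n_zw_sites > 0:
            raise ValueError("n_zw_sites > 0 requires a sex_region")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for one operation, derived from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class TruthTable:
    """Ground truth of a simulated chromosome, for recovery testing.

    ``sites`` has one row per variable site: ``pos`` (0-based), ``ref``,
    ``alt``, ``freq_male``/``freq_female`` (population frequency of ``alt``
    in each sex) and ``is_zw``. At ZW sites the alt (W) allele sits at 0.5 in
    females and 0.0 in males before any sampling noise.
    """

    chrom: str
    sites: pd.DataFrame
    sex_region: Interval | None
    inversion_segment: Interval | None
    te_intervals: list[Interval] = field(default_factory=list)

    @property
    def zw_site_positions(self) -> np.ndarray:
        return self.sites.loc[self.sites["is_zw"], "pos"].to_numpy()


def simulate_population(config: SimConfig) -> TruthTable:
    """Draw the variable sites of one synthetic population.

    Background SNPs have sex-independent frequencies uniform on [0.05, 0.95];
    ZW sites have female W frequency 0.5 and male 0.0. Deterministic for a
    fixed config seed.
    """
    rng = config.rng("population")
    positions: list[np.ndarray] = []

    zw_pos = np.empty(0, dtype=np.int64)
    if config.n_zw_sites > 0:
        assert config.sex_region is not None  # enforced by SimConfig
        lo, hi = config.sex_region
        zw_pos = np.sort(
            rng.choice(hi - lo, size=config.n_zw_sites, replace=False) + lo
        )
    taken = set(zw_pos.tolist())
    bg_pos = np.empty(0, dtype=np.int64)
    if config.n_background_snps > 0:
        draws: list[int] = []
        while len(draws) < config.n_background_snps:
            cand = rng.integers(0, config.genome_length, size=config.n_background_snps)
            for p in cand.tolist():
                if p not in taken:
                    taken.add(p)
                    draws.append(p)
                    if len(draws) == config.n_background_snps:
                        break
        bg_pos = np.sort(np.asarray(draws, dtype=np.int64))

    pos = np.concatenate([zw_pos, bg_pos])
    is_zw = np.concatenate(
        [np.ones(len(zw_pos), bool), np.zeros(len(bg_pos), bool)]
    )
    order = np.argsort(pos, kind="stable")
    pos, is_zw = pos[order], is_zw[order]

    n = len(pos)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    nts = np.array(NUCLEOTIDES)
    ref = nts[ref_idx]
    alt = nts[(ref_idx + alt_shift) % 4]

    bg_freq = rng.uniform(0.05, 0.95, size=n)
    freq_male = np.where(is_zw, 0.0, bg_freq)
    freq_female = np.where(is_zw, 0.5, bg_freq)

    sites = pd.DataFrame(
        {
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "freq_male": freq_male,
            "freq_female": freq_female,
            "is_zw": is_zw,
        }
    )
    return TruthTable(
        chrom=config.chrom,
        sites=sites,
        sex_region=config.sex_region,
        inversion_segment=config.inversion_segment,
        te_intervals=simulate_te_intervals(config),
    )


def simulate_pooled_counts(
    truth: TruthTable, config: SimConfig
) -> Iterator[PooledSiteCounts]:
    """Sample sync-style read counts for the male (pool 1) and female (pool 2) pools.

    Per site and pool: 2 * pool_size gene copies are drawn from the sex's
    population frequency, depth ~ Poisson(pool_size * per_individual_coverage),
    and alt reads ~ Binomial(depth, realised pool frequency). Counts over
    {A,C,G,T} sum exactly to the sampled depth.
    """
    rng = config.rng("counts")
    copies = 2 * config.pool_size
    mean_depth = config.pool_size * config.per_individual_coverage
    for row in truth.sites.itertuples(index=False):
        counts_by_pool: list[dict[str, int]] = []
        for pop_freq in (row.freq_male, row.freq_female):
            pool_freq = rng.binomial(copies, pop_freq) / copies
            depth = int(rng.poisson(mean_depth))
            alt_reads = int(rng.binomial(depth, pool_freq)) if depth > 0 else 0
            counts: dict[str, int] = {}
            if depth - alt_reads > 0:
                counts[row.ref] = depth - alt_reads
            if alt_reads > 0:
                counts[row.alt] = alt_reads
            counts_by_pool.append(counts)
        yield PooledSiteCounts(
            chrom=truth.chrom,
            pos=int(row.pos) + 1,  # sync positions are 1-based
            ref=row.ref,
            counts_pool1=counts_by_pool[0],
            counts_pool2=counts_by_pool[1],
        )


# element size for Bernoulli TE placement; small enough that per-window
# fractions are fine-grained, large enough to keep 31 Mb genomes cheap
_TE_SEGMENT = 100


def simulate_te_intervals(config: SimConfig) -> list[Interval]:
    """Place TE intervals segment-by-segment and merge adjacent ones.

    The genome is tiled into 100 bp segments; each becomes TE with
    probability te_base_rate, or te_peak_rate if it lies inside a peak
    interval, so the expected per-bp TE fraction equals the local rate.
    """
    rng = config.rng("te")
    n_seg = -(-config.genome_length // _TE_SEGMENT)  # ceil
    starts = np.arange(n_seg, dtype=np.int64) * _TE_SEGMENT
    rates = np.full(n_seg, config.te_base_rate)
    for lo, hi in config.te_peak_intervals:
        in_peak = (starts >= lo) & (starts < hi)
        rates[in_peak] = config.te_peak_rate
    hits = rng.random(n_seg) < rates
    intervals: list[Interval] = []
    for i in np.flatnonzero(hits):
        s = int(starts[i])
        e = min(s + _TE_SEGMENT, config.genome_length)
        if intervals and intervals[-1][1] == s:
            intervals[-1] = (intervals[-1][0], e)
        else:
            intervals.append((s, e))
    return intervals


def simulate_alignment_blocks(
    truth: TruthTable,
    config: SimConfig | None = None,
    n_inversion_blocks: int = 1,
    breakpoint_jitter: int = 0,
    query_name: str = "alt_hap",
) -> list[AlignmentBlock]:
    """Emit collinear alignment blocks for an identity-plus-inversion alignment.

    Forward blocks cover the genome outside the inversion segment, which is
    emitted as ``n_inversion_blocks`` reverse-orientation blocks. The query
    haplotype carries ``query_expansion_bp`` of extra length spread across the
    reverse blocks, emulating repeat expansion inside the inverted haplotype.
    ``breakpoint_jitter`` randomly trims up to that many bp off each block
    edge (independent noise per "species" assembly).
    """
    expansion = config.query_expansion_bp if config is not None else 1_300_000
    rng = (
        config.rng("blocks")
        if config is not None
        else np.random.default_rng(0)
    )
    genome_length = (
        config.genome_length
        if config is not None
        else int(truth.sites["pos"].max()) + 1
        if len(truth.sites)
        else 0
    )
    chrom = truth.chrom
    blocks: list[AlignmentBlock] = []

    def jitter() -> int:
        return int(rng.integers(0, breakpoint_jitter + 1)) if breakpoint_jitter else 0

    if truth.inversion_segment is None:
        blocks.append(
            AlignmentBlock(chrom, 0, genome_length, query_name, 0, genome_length, "+")
        )
        return blocks

    inv_s, inv_e = truth.inversion_segment
    # query coordinates track target until the inversion, which is longer on
    # the query side by `expansion`
    if inv_s > 0:
        a, b = jitter(), jitter()
        blocks.append(
            AlignmentBlock(chrom, 0 + a, inv_s - b, query_name, 0 + a, inv_s - b, "+")
        )
    target_span = inv_e - inv_s
    query_span = target_span + expansion
    piece_t = target_span // n_inversion_blocks
    piece_q = query_span // n_inversion_blocks
    for i in range(n_inversion_blocks):
        t0 = inv_s + i * piece_t
        t1 = inv_e if i == n_inversion_blocks - 1 else t0 + piece_t
        q0 = inv_s + i * piece_q
        q1 = inv_s + query_span if i == n_inversion_blocks - 1 else q0 + piece_q
        a, b = jitter(), jitter()
        blocks.append(
            AlignmentBlock(chrom, t0 + a, t1 - b, query_name, q0 + a, q1 - b, "-")
        )
    if inv_e < genome_length:
        a, b = jitter(), jitter()
        blocks.append(
            AlignmentBlock(
                chrom,
                inv_e + a,
                genome_length - b,
                query_name,
                inv_e + expansion + a,
                genome_length + expansion - b,
                "+",
            )
        )
    return blocks


def write_blocks_tsv(path: str | Path, blocks: Sequence[AlignmentBlock]) -> None:
    """Block TSV: target_start target_end query_start query_end strand names."""
    with open(path, "w") as fh:
        fh.write(
            "target_start\ttarget_end\tquery_start\tquery_end\tstrand"
            "\ttarget_name\tquery_name\n"
        )
        for b in blocks:
            fh.write(
                f"{b.target_start}\t{b.target_end}\t{b.query_start}\t{b.query_end}"
                f"\t{b.strand}\t{b.target_chrom}\t{b.query_chrom}\n"
            )


def write_truth(truth: TruthTable, yaml_path: str | Path, sites_path: str | Path) -> None:
    """Sidecar pair: scalar truth as YAML, per-site truth as TSV."""
    meta = {
        "chrom": truth.chrom,
        "sex_region": list(truth.sex_region) if truth.sex_region else None,
        "inversion_segment": (
            list(truth.inversion_segment) if truth.inversion_segment else None
        ),
        "n_zw_sites": int(truth.sites["is_zw"].sum()),
        "n_sites": int(len(truth.sites)),
        "te_intervals": [list(iv) for iv in truth.te_intervals],
    }
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    truth.sites.to_csv(sites_path, sep="\t", index=False)


def read_truth(yaml_path: str | Path, sites_path: str | Path) -> TruthTable:
    with open(yaml_path) as fh:
        meta = yaml.safe_load(fh)
    sites = pd.read_csv(sites_path, sep="\t")
    return TruthTable(
        chrom=meta["chrom"],
        sites=sites,
        sex_region=tuple(meta["sex_region"]) if meta["sex_region"] else None,
        inversion_segment=(
            tuple(meta["inversion_segment"]) if meta["inversion_segment"] else None
        ),
        te_intervals=[tuple(iv) for iv in meta.get("te_intervals", [])],
    )
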