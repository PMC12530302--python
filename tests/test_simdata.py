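import numpy as np
import pandas as pd
import pytest

from zwscan import (
    SimConfig,
    simulate_alignment_blocks,
    simulate_pooled_counts,
    simulate_population,
    simulate_te_intervals,
)
from zwscan.simdata import read_truth, write_blocks_tsv, write_truth


class TestConfigValidation:
    def test_zw_sites_require_sex_region(self):
        with pytest.raises(ValueError, match="sex_region"):
            SimConfig(sex_region=None, n_zw_sites=10)

    def test_interval_bounds_checked(self):
        with pytest.raises(ValueError, match="interval"):
            SimConfig(genome_length=1000, sex_region=(500, 2000), te_peak_intervals=[])

    @pytest.mark.parametrize("field,value", [("te_base_rate", 1.5), ("pool_size", 0)])
    def test_rates_and_pool_size(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})


class TestSimulatePopulation:
    def test_seed_determinism_across_all_operations(self, small_config):
        t1, t2 = (simulate_population(small_config) for _ in range(2))
        pd.testing.assert_frame_equal(t1.sites, t2.sites)
        assert t1.te_intervals == t2.te_intervals
        c1 = list(simulate_pooled_counts(t1, small_config))
        c2 = list(simulate_pooled_counts(t2, small_config))
        assert c1 == c2
        assert simulate_alignment_blocks(t1, small_config) == simulate_alignment_blocks(
            t2, small_config
        )

    def test_no_zw_sites_gives_empty_positions(self):
        config = SimConfig(n_zw_sites=0, seed=3)
        truth = simulate_population(config)
        assert len(truth.zw_site_positions) == 0

    def test_all_zw_positions_inside_sex_region(self):
        config = SimConfig(n_zw_sites=500, seed=5)
        truth = simulate_population(config)
        lo, hi = config.sex_region
        pos = truth.zw_site_positions
        assert len(pos) == 500
        assert ((pos >= lo) & (pos < hi)).all()

    def test_population_frequencies(self, small_truth):
        zw = small_truth.sites[small_truth.sites["is_zw"]]
        bg = small_truth.sites[~small_truth.sites["is_zw"]]
        assert (zw["freq_female"] == 0.5).all() and (zw["freq_male"] == 0.0).all()
        assert (bg["freq_male"] == bg["freq_female"]).all()
        assert bg["freq_male"].between(0.05, 0.95).all()
        assert small_truth.sites["pos"].is_unique


class TestSimulatePooledCounts:
    def test_counts_conserve_depth(self, small_config, small_truth):
        # counts live on {ref, alt} only and are strictly positive, so the
        # nucleotide sum is exactly the sampled depth at every site
        for site in simulate_pooled_counts(small_truth, small_config):
            assert all(v > 0 for v in site.counts_pool1.values())
            assert all(v > 0 for v in site.counts_pool2.values())
            # counts are only over {ref, alt}; sums are the sampled depths
            assert set(site.counts_pool1) | set(site.counts_pool2) <= set("ACGT")

    def test_monomorphic_background_site_single_nucleotide(self):
        config = SimConfig(
            genome_length=10_000,
            sex_region=None,
            n_zw_sites=0,
            n_background_snps=50,
            per_individual_coverage=5.0,
            inversion_segment=None,
            te_peak_intervals=[],
            seed=1,
        )
        truth = simulate_population(config)
        truth.sites["freq_male"] = 0.0  # force monomorphic for ref
        truth.sites["freq_female"] = 0.0
        for site in simulate_pooled_counts(truth, config):
            for counts in (site.counts_pool1, site.counts_pool2):
                assert len(counts) <= 1
                assert set(counts) <= {site.ref}

    def test_zw_female_frequency_concentrates_at_half(self):
        """Mean female W frequency over 100 deep ZW sites lands in 0.45-0.55."""
        config = SimConfig(
            genome_length=1_000_000,
            sex_region=(0, 1_000_000),
            n_zw_sites=100,
            n_background_snps=0,
            per_individual_coverage=100.0,  # pooled depth ~2000
            inversion_segment=None,
            te_peak_intervals=[],
            seed=9,
        )
        truth = simulate_population(config)
        freqs = []
        for site in simulate_pooled_counts(truth, config):
            row = truth.sites.loc[truth.sites["pos"] == site.pos - 1].iloc[0]
            depth = site.depth(2)
            assert depth >= 1500
            freqs.append(site.counts_pool2.get(row["alt"], 0) / depth)
        assert len(freqs) == 100
        assert 0.45 <= np.mean(freqs) <= 0.55

    def test_frequency_calibration_improves_with_depth(self):
        """Mean |pool read freq - truth freq| shrinks from depth 20 to 2000."""
        base = dict(
            genome_length=2_000_000,
            sex_region=None,
            n_zw_sites=0,
            n_background_snps=1000,
            inversion_segment=None,
            te_peak_intervals=[],
            seed=13,
        )
        deviations = {}
        for coverage in (1.0, 100.0):
            config = SimConfig(per_individual_coverage=coverage, **base)
            truth = simulate_population(config)
            alt_by_pos = dict(zip(truth.sites["pos"], truth.sites["alt"]))
            freq_by_pos = dict(zip(truth.sites["pos"], truth.sites["freq_male"]))
            devs = []
            for site in simulate_pooled_counts(truth, config):
                d = site.depth(1)
                if d == 0:
                    continue
                realised = site.counts_pool1.get(alt_by_pos[site.pos - 1], 0) / d
                devs.append(abs(realised - freq_by_pos[site.pos - 1]))
            deviations[coverage] = np.mean(devs)
        assert deviations[100.0] < deviations[1.0]


class TestSimulateTeIntervals:
    def test_zero_rate_no_peaks_gives_empty(self):
        config = SimConfig(te_base_rate=0.0, te_peak_intervals=[], seed=2,
                           genome_length=100_000, sex_region=None, n_zw_sites=0,
                           inversion_segment=None)
        assert simulate_te_intervals(config) == []

    def test_saturated_peak_fully_covered(self):
        config = SimConfig(
            genome_length=1_000_000,
            sex_region=None,
            n_zw_sites=0,
            inversion_segment=None,
            te_base_rate=0.0,
            te_peak_rate=1.0,
            te_peak_intervals=[(200_000, 400_000)],
            seed=2,
        )
        intervals = simulate_te_intervals(config)
        assert intervals == [(200_000, 400_000)]

    def test_genome_wide_fraction_law_of_large_numbers(self):
        config = SimConfig(
            genome_length=10_000_000,
            sex_region=None,
            n_zw_sites=0,
            inversion_segment=None,
            te_base_rate=0.25,
            te_peak_intervals=[],
            seed=4,
        )
        intervals = simulate_te_intervals(config)
        covered = sum(e - s for s, e in intervals)
        assert 0.23 <= covered / config.genome_length <= 0.27
        starts = [s for s, _ in intervals]
        assert starts == sorted(starts)
        assert all(a[1] < b[0] for a, b in zip(intervals, intervals[1:]))


class TestSimulateAlignmentBlocks:
    def test_no_inversion_identity_alignment(self):
        config = SimConfig(sex_region=None, n_zw_sites=0, inversion_segment=None,
                           te_peak_intervals=[], genome_length=5_000_000, seed=1)
        truth = simulate_population(config)
        blocks = simulate_alignment_blocks(truth, config)
        assert all(b.strand == "+" for b in blocks)
        assert all(
            (b.query_start, b.query_end) == (b.target_start, b.target_end)
            for b in blocks
        )

    def test_inversion_span_covered_by_reverse_blocks(self, small_config):
        truth = simulate_population(small_config)
        blocks = simulate_alignment_blocks(truth, small_config, n_inversion_blocks=3)
        minus = sorted(
            (b for b in blocks if b.strand == "-"), key=lambda b: b.target_start
        )
        lo, hi = small_config.inversion_segment
        assert minus[0].target_start == lo and minus[-1].target_end == hi
        assert all(a.target_end == b.target_start for a, b in zip(minus, minus[1:]))

    def test_query_expansion_bookkeeping(self):
        """A 1.3 Mb configured repeat insertion makes the inverted query span
        exceed the target span by exactly 1.3 Mb."""
        config = SimConfig(seed=6)  # default expansion 1.3 Mb
        truth = simulate_population(config)
        blocks = simulate_alignment_blocks(truth, config)
        minus = [b for b in blocks if b.strand == "-"]
        t_span = max(b.target_end for b in minus) - min(b.target_start for b in minus)
        q_span = max(b.query_end for b in minus) - min(b.query_start for b in minus)
        assert q_span - t_span == 1_300_000


def test_truth_and_blocks_round_trip(tmp_path, small_config, small_truth):
    write_truth(small_truth, tmp_path / "t.yaml", tmp_path / "t.tsv")
    back = read_truth(tmp_path / "t.yaml", tmp_path / "t.tsv")
    assert back.sex_region == small_truth.sex_region
    assert back.inversion_segment == small_truth.inversion_segment
    assert back.te_intervals == small_truth.te_intervals
    pd.testing.assert_frame_equal(back.sites, small_truth.sites)

    from zwscan.inversion import read_blocks

    blocks = simulate_alignment_blocks(small_truth, small_config)
    write_blocks_tsv(tmp_path / "b.tsv", blocks)
    assert read_blocks(tmp_path / "b.tsv", dialect="tsv") == blocks
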