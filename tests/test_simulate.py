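import numpy as np
import pytest

from gahd.expression import log2_ratio
from gahd.intervals import overlap_length
from gahd.methylation import HYPER, classify_regions
from gahd.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_gahd_tracks,
    simulate_genome,
    simulate_mark_tracks,
    simulate_methylation,
)


class TestSimulateGenome:
    def test_zero_genes(self):
        cfg = SimulationConfig(n_genes=0, n_chroms=1, chrom_length=10**6)
        assert simulate_genome(cfg).genes == []

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=5, n_chroms=1, chrom_length=10**6, n_genes=20)
        g1, g2 = simulate_genome(cfg), simulate_genome(cfg)
        assert g1.genes == g2.genes

    def test_genes_fit_without_overlap(self):
        cfg = SimulationConfig(seed=2)
        genes = simulate_genome(cfg).genes
        assert len(genes) == 200
        for a, b in zip(genes, genes[1:]):
            assert overlap_length(a.interval, b.interval) == 0

    def test_infeasible_packing_raises(self):
        cfg = SimulationConfig(
            n_chroms=1, chrom_length=100_000, n_genes=50, gene_length=(30_000, 40_000)
        )
        with pytest.raises(ValueError, match="pack"):
            simulate_genome(cfg)


class TestGahdTracks:
    def test_deterministic_under_seed(self, small_config):
        genome = simulate_genome(small_config)
        t1, truth1 = simulate_gahd_tracks(small_config, genome)
        t2, truth2 = simulate_gahd_tracks(small_config, genome)
        assert truth1.degraded_regions_wt == truth2.degraded_regions_wt
        for name in t1:
            np.testing.assert_array_equal(t1[name].values["chr1"], t2[name].values["chr1"])

    def test_truth_structure(self, small_study):
        cfg, genome, tracks, truth = small_study
        assert len(truth.degraded_regions_wt) == cfg.n_degraded_regions
        assert len(truth.pa200_dependent_regions) == cfg.n_pa200_dependent
        wt = {(r.chrom, r.start, r.end) for r in truth.degraded_regions_wt}
        assert all((r.chrom, r.start, r.end) in wt for r in truth.pa200_dependent_regions)
        # regions within a list do not overlap
        for a, b in zip(truth.degraded_regions_wt, truth.degraded_regions_wt[1:]):
            assert overlap_length(a, b) == 0

    def test_retained_fraction_recovered(self, small_study):
        """Mean 4h/0h ratio over WT planted regions sits near the planted 0.2."""
        cfg, genome, tracks, truth = small_study
        ratios = []
        for r in truth.degraded_regions_wt:
            m0 = tracks["WT0h"].range_mean(r.chrom, r.start, r.end)
            m4 = tracks["WT4h"].range_mean(r.chrom, r.start, r.end)
            ratios.append(m4 / m0)
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - cfg.degraded_fraction_retained_4h_wt) <= 3 * se + 0.01

    def test_no_degradation_limit(self):
        """Retained fractions of 1.0 leave planted regions unchanged on average."""
        cfg = SimulationConfig(
            n_chroms=1, chrom_length=2_000_000, n_genes=40,
            n_degraded_regions=12, n_pa200_dependent=8,
            degraded_fraction_retained_4h_wt=1.0,
            degraded_fraction_retained_4h_ko=1.0, seed=3,
        )
        genome = simulate_genome(cfg)
        tracks, truth = simulate_gahd_tracks(cfg, genome)
        ms = []
        for r in truth.degraded_regions_wt:
            m0 = tracks["WT0h"].range_mean(r.chrom, r.start, r.end)
            m4 = tracks["WT4h"].range_mean(r.chrom, r.start, r.end)
            ms.append(np.log2(m0 / m4))
        assert abs(np.mean(ms)) < 0.1


class TestMarkTracks:
    def test_up_genes_have_higher_ko_ratio_than_down(self, small_study):
        cfg, genome, tracks, truth = small_study
        marks = simulate_mark_tracks(cfg, genome, truth)
        wt, ko = marks["H3K56ac"]["WT"], marks["H3K56ac"]["KO"]

        def mean_ratio(ids):
            vals = []
            for g in genome.genes:
                if g.gene_id in ids:
                    iv = g.interval
                    vals.append(
                        ko.range_mean(iv.chrom, iv.start, iv.end)
                        / wt.range_mean(iv.chrom, iv.start, iv.end)
                    )
            return np.mean(vals)

        up = mean_ratio(set(truth.deg_up_ids))
        down = mean_ratio(set(truth.deg_down_ids))
        other = mean_ratio(
            {g.gene_id for g in genome.genes}
            - set(truth.deg_up_ids)
            - set(truth.deg_down_ids)
        )
        assert up > other > down
        assert up > 1.5 and down < 0.75

    def test_no_deg_classes_gives_flat_ratios(self):
        cfg = SimulationConfig(
            n_chroms=1, chrom_length=2_000_000, n_genes=40,
            n_degraded_regions=4, n_pa200_dependent=2,
            n_deg_up=0, n_deg_down=0, seed=9,
        )
        genome = simulate_genome(cfg)
        _, truth = simulate_gahd_tracks(cfg, genome)
        marks = simulate_mark_tracks(cfg, genome, truth)
        wt, ko = marks["H3K4me3"]["WT"], marks["H3K4me3"]["KO"]
        ratios = [
            ko.range_mean(g.interval.chrom, g.interval.start, g.interval.end)
            / wt.range_mean(g.interval.chrom, g.interval.start, g.interval.end)
            for g in genome.genes
        ]
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_h3_identical_rates_between_genotypes(self, small_study):
        cfg, genome, tracks, truth = small_study
        marks = simulate_mark_tracks(cfg, genome, truth)
        wt_mean = marks["H3"]["WT"].library_size
        ko_mean = marks["H3"]["KO"].library_size
        assert abs(wt_mean - ko_mean) / wt_mean < 0.01


class TestMethylation:
    def exception_fraction_run(self, fraction, seed=1):
        cfg = SimulationConfig(
            n_chroms=1, chrom_length=2_000_000, n_genes=40,
            n_degraded_regions=12, n_pa200_dependent=10,
            n_hyper_domains=4, hyper_exception_fraction=fraction, seed=seed,
        )
        genome = simulate_genome(cfg)
        _, truth = simulate_gahd_tracks(cfg, genome)
        meth = simulate_methylation(cfg, genome, truth)
        counts, _ = classify_regions(truth.pa200_dependent_regions, meth)
        return counts, truth

    def test_exception_zero_gives_no_hyper_regions(self):
        counts, _ = self.exception_fraction_run(0.0)
        assert counts[HYPER] == 0

    def test_exception_one_gives_all_hyper(self):
        counts, truth = self.exception_fraction_run(1.0)
        assert counts[HYPER] == len(truth.pa200_dependent_regions)

    def test_default_exception_matches_planted_rate(self, small_study):
        cfg, genome, tracks, truth = small_study
        meth = simulate_methylation(cfg, genome, truth)
        counts, _ = classify_regions(truth.pa200_dependent_regions, meth)
        n = len(truth.pa200_dependent_regions)
        expected = round(cfg.hyper_exception_fraction * n)
        assert counts[HYPER] == expected

    def test_hyper_domain_levels_exceed_half(self, small_study):
        cfg, genome, tracks, truth = small_study
        meth = simulate_methylation(cfg, genome, truth)
        counts, labels = classify_regions(truth.hyper_domains, meth)
        assert counts[HYPER] == len(truth.hyper_domains)


class TestCounts:
    def test_deterministic_under_seed(self, small_study):
        cfg, genome, tracks, truth = small_study
        t1 = simulate_counts(cfg, genome, truth)
        t2 = simulate_counts(cfg, genome, truth)
        np.testing.assert_array_equal(t1.counts_a, t2.counts_a)
        np.testing.assert_array_equal(t1.counts_b, t2.counts_b)

    def test_planted_fold_change_recovered(self):
        cfg = SimulationConfig(seed=2)
        genome = simulate_genome(cfg)
        _, truth = simulate_gahd_tracks(cfg, genome)
        table = simulate_counts(cfg, genome, truth)
        idx = {g: i for i, g in enumerate(table.gene_ids)}
        lrs = [
            log2_ratio(
                table.counts_a[idx[g]],
                table.counts_b[idx[g]],
                table.library_size_a,
                table.library_size_b,
            )
            for g in truth.deg_up_ids
        ]
        assert abs(np.median(lrs) - cfg.deg_log2fc) <= 0.3

    def test_library_sizes_within_twofold(self):
        cfg = SimulationConfig(seed=8)
        genome = simulate_genome(cfg)
        _, truth = simulate_gahd_tracks(cfg, genome)
        table = simulate_counts(cfg, genome, truth)
        ratio = table.library_size_b / table.library_size_a
        assert 0.5 <= ratio <= 2.0
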