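import numpy as np
import pytest

from gahd.intervals import GeneAnnotation, GenomicInterval, SignalTrack
from gahd.profiles import column_summary, metagene_matrix, ratio_profile, tss_signal

from conftest import per_base_values


def gene(chrom, start, end, strand="+", gid="g"):
    return GeneAnnotation(GenomicInterval(chrom, start, end, strand), gid)


def constant_track(value=3.0, size=100_000, bin_size=50):
    return SignalTrack({"chr1": np.full(size // bin_size, value)}, bin_size, {"chr1": size})


class TestMetageneMatrix:
    def test_constant_track_fills_every_cell(self):
        track = constant_track(3.0)
        genes = [gene("chr1", 30_000, 45_000), gene("chr1", 60_000, 70_000, "-")]
        mat = metagene_matrix(track, genes, flank=6000, n_body_bins=50, flank_bin=300)
        assert mat.values.shape == (2, 20 + 50 + 20)
        np.testing.assert_allclose(mat.values, 3.0)

    def test_strand_flip_puts_tss_signal_in_same_column(self):
        """A delta at the TSS lands at the upstream body boundary both strands."""
        size, b = 100_000, 50
        v_plus = np.zeros(size // b)
        v_plus[30_000 // b] = 100.0  # at plus-strand TSS (start)
        v_minus = np.zeros(size // b)
        v_minus[(70_000 - b) // b] = 100.0  # at minus-strand TSS (end)
        track_p = SignalTrack({"chr1": v_plus}, b, {"chr1": size})
        track_m = SignalTrack({"chr1": v_minus}, b, {"chr1": size})
        g_plus = gene("chr1", 30_000, 40_000, "+")
        g_minus = gene("chr1", 60_000, 70_000, "-")
        mat_p = metagene_matrix(track_p, [g_plus], flank=3000, n_body_bins=100, flank_bin=300)
        mat_m = metagene_matrix(track_m, [g_minus], flank=3000, n_body_bins=100, flank_bin=300)
        assert np.nanargmax(mat_p.values[0]) == np.nanargmax(mat_m.values[0]) == 10

    def test_matches_per_base_oracle(self):
        """50 random genes vs explicit per-base averaging."""
        rng = np.random.default_rng(44)
        size, b = 300_000, 50
        track = SignalTrack(
            {"chr1": rng.poisson(5.0, size // b).astype(float)}, b, {"chr1": size}
        )
        base = per_base_values(track, "chr1")
        flank, n_body, fbin = 3000, 40, 300
        genes = []
        for i in range(50):
            start = int(rng.integers(flank, size - flank - 20_000))
            length = int(rng.integers(500, 15_000))
            genes.append(
                gene("chr1", start, start + length, "+-"[rng.integers(2)], f"g{i}")
            )
        mat = metagene_matrix(track, genes, flank=flank, n_body_bins=n_body, flank_bin=fbin)
        for row, g in zip(mat.values, genes):
            iv = g.interval
            segs = []
            for k in range(flank // fbin):
                s = iv.start - flank + k * fbin
                segs.append(base[s : s + fbin].mean())
            bounds = [iv.start + round(i * iv.length / n_body) for i in range(n_body + 1)]
            for i in range(n_body):
                segs.append(base[bounds[i] : bounds[i + 1]].mean())
            for k in range(flank // fbin):
                s = iv.end + k * fbin
                segs.append(base[s : s + fbin].mean())
            expected = np.array(segs)
            if g.strand == "-":
                expected = expected[::-1]
            np.testing.assert_allclose(row, expected, atol=1e-9)

    def test_short_genes_are_skipped(self):
        track = constant_track()
        genes = [gene("chr1", 30_000, 30_050)]  # 50 bp < 100 body bins
        mat = metagene_matrix(track, genes, flank=3000, n_body_bins=100, flank_bin=300)
        assert mat.n_skipped == 1 and mat.values.shape[0] == 0

    def test_out_of_bounds_cells_are_nan(self):
        track = constant_track(size=50_000)
        mat = metagene_matrix(
            track, [gene("chr1", 1000, 11_000)], flank=3000, n_body_bins=20, flank_bin=300
        )
        assert np.isnan(mat.values[0, :6]).all()  # flank reaches below 0
        assert np.isfinite(mat.values[0, 10:]).all()

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        track = SignalTrack({"chr1": rng.poisson(4.0, 2000).astype(float)}, 50)
        genes = [gene("chr1", 10_000 + 15_000 * i, 20_000 + 15_000 * i, gid=f"g{i}") for i in range(4)]
        m1 = column_summary(metagene_matrix(track, genes, flank=3000, n_body_bins=30))
        m2 = column_summary(metagene_matrix(track, genes[::-1], flank=3000, n_body_bins=30))
        np.testing.assert_allclose(m1, m2)

    def test_depth_scaling_is_exact(self):
        rng = np.random.default_rng(2)
        track = SignalTrack({"chr1": rng.poisson(4.0, 2000).astype(float)}, 50)
        genes = [gene("chr1", 20_000, 50_000)]
        m1 = metagene_matrix(track, genes, flank=3000, n_body_bins=30)
        m2 = metagene_matrix(track.scaled(7.0), genes, flank=3000, n_body_bins=30)
        np.testing.assert_allclose(m2.values, 7.0 * m1.values, rtol=1e-12)

    def test_coordinate_reversal_symmetry(self):
        """Reversing the chromosome and flipping strands leaves profiles unchanged."""
        rng = np.random.default_rng(10)
        size, b = 100_000, 50
        values = rng.poisson(5.0, size // b).astype(float)
        track = SignalTrack({"chr1": values}, b, {"chr1": size})
        track_rev = SignalTrack({"chr1": values[::-1].copy()}, b, {"chr1": size})
        genes = [gene("chr1", 20_000, 35_000, "+"), gene("chr1", 50_000, 61_000, "-")]
        genes_rev = [
            gene("chr1", size - g.interval.end, size - g.interval.start,
                 "-" if g.strand == "+" else "+", g.gene_id)
            for g in genes
        ]
        m1 = metagene_matrix(track, genes, flank=3000, n_body_bins=50, flank_bin=300)
        m2 = metagene_matrix(track_rev, genes_rev, flank=3000, n_body_bins=50, flank_bin=300)
        np.testing.assert_allclose(
            np.sort(m1.values, axis=0), np.sort(m2.values, axis=0), atol=1e-9
        )


class TestColumnSummaryAndRatio:
    def test_single_gene_summary_is_the_row(self):
        track = constant_track(2.5)
        mat = metagene_matrix(track, [gene("chr1", 30_000, 45_000)], flank=3000, n_body_bins=30)
        np.testing.assert_allclose(column_summary(mat), mat.values[0])

    def test_equal_matrices_give_zero_profile(self):
        track = constant_track(2.0)
        mat = metagene_matrix(track, [gene("chr1", 30_000, 45_000)], flank=3000, n_body_bins=30)
        np.testing.assert_allclose(ratio_profile(mat, mat), 0.0)

    def test_twofold_gives_one_with_small_pseudocount(self):
        t1 = constant_track(50.0)
        t2 = constant_track(100.0)
        genes = [gene("chr1", 30_000, 45_000)]
        m1 = metagene_matrix(t1, genes, flank=3000, n_body_bins=30)
        m2 = metagene_matrix(t2, genes, flank=3000, n_body_bins=30)
        np.testing.assert_allclose(ratio_profile(m2, m1, pseudocount=0.01), 1.0, atol=0.01)

    def test_double_normalization_cancels_reference(self):
        mark_wt = constant_track(10.0)
        mark_ko = constant_track(40.0)
        h3_wt = constant_track(2.0)
        h3_ko = constant_track(4.0)  # KO H3 doubled: mark/H3 ratio becomes 2, not 4
        genes = [gene("chr1", 30_000, 45_000)]

        def mat(t):
            return metagene_matrix(t, genes, flank=3000, n_body_bins=30)

        profile = ratio_profile(
            mat(mark_ko), mat(mark_wt), pseudocount=0.001,
            numerator_reference=mat(h3_ko), denominator_reference=mat(h3_wt),
        )
        np.testing.assert_allclose(profile, 1.0, atol=0.01)

    def test_geometry_mismatch_raises(self):
        track = constant_track()
        genes = [gene("chr1", 30_000, 45_000)]
        m1 = metagene_matrix(track, genes, flank=3000, n_body_bins=30)
        m2 = metagene_matrix(track, genes, flank=3000, n_body_bins=40)
        with pytest.raises(ValueError):
            ratio_profile(m1, m2)


class TestTssSignal:
    def test_constant_track_promoter_mean(self):
        track = constant_track(4.0)
        _, means, _ = tss_signal(track, [gene("chr1", 30_000, 45_000)])
        assert means[0] == pytest.approx(4.0)

    def test_delta_at_tss_lands_in_center_bin(self):
        size, b = 100_000, 50
        v = np.zeros(size // b)
        v[30_000 // b] = 99.0
        track = SignalTrack({"chr1": v}, b, {"chr1": size})
        rows, _, _ = tss_signal(track, [gene("chr1", 30_000, 45_000)], half_width=500, bin=50)
        assert np.argmax(rows[0]) == 10  # first bin downstream of the TSS

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(77)
        size, b = 200_000, 50
        track = SignalTrack(
            {"chr1": rng.poisson(6.0, size // b).astype(float)}, b, {"chr1": size}
        )
        base = per_base_values(track, "chr1")
        genes = []
        for i in range(60):
            start = int(rng.integers(5000, size - 25_000))
            genes.append(gene("chr1", start, start + 10_000, "+-"[rng.integers(2)], f"g{i}"))
        rows, means, _ = tss_signal(track, genes, half_width=2500, bin=50)
        for row, mean, g in zip(rows, means, genes):
            tss = g.tss
            window = base[tss - 2500 : tss + 2500]
            expected = window.reshape(-1, 50).mean(axis=1)
            if g.strand == "-":
                expected = expected[::-1]
            np.testing.assert_allclose(row, expected, atol=1e-9)
            assert mean == pytest.approx(window.mean(), abs=1e-9)
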