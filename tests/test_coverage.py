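"""Coverage ingestion from SAM/BAM, tracks and BED, backends, and caching."""

import numpy as np
import pytest

from seqcover.coverage import (
    CoverageDataset,
    aggregate_windows,
    coverage_from_bam,
    coverage_from_bed,
    coverage_from_bigwig,
)
from seqcover.intervals import (
    ChromSizes,
    GenomicInterval,
    RegionSet,
    label_by_overlap,
    tile,
)
from seqcover.storage import CacheKey, load_or_build

SIZES = ChromSizes({"chr1": 1000})


def one_window_grid(binsize=200, flank=0, sizes=SIZES):
    r = RegionSet([GenomicInterval("chr1", 0, binsize)], sizes)
    return tile(r, binsize, binsize, flank=flank)


def write_sam(path, reads, sizes=SIZES):
    """reads: (chrom, start_0based, read_len, is_reverse)."""
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for c in sizes:
        lines.append(f"@SQ\tSN:{c}\tLN:{sizes[c]}")
    for i, (chrom, start, rl, rev) in enumerate(reads):
        flag = 16 if rev else 0
        lines.append(
            f"r{i}\t{flag}\t{chrom}\t{start + 1}\t60\t{rl}M\t*\t0\t0\t{'A' * rl}\t*"
        )
    path.write_text("\n".join(lines) + "\n")


class TestCoverageFromBam:
    def test_forward_read_counts_at_leftmost_base_bin(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [("chr1", 10, 50, False)])  # aligned [10,60), 5' end 10
        ds = coverage_from_bam(sam, one_window_grid(), resolution=50)
        assert ds.values[0, :, 0, 0].tolist() == [1, 0, 0, 0]

    def test_reverse_read_counts_at_rightmost_base_bin(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [("chr1", 100, 50, True)])  # aligned [100,150), 5' end 149
        ds = coverage_from_bam(sam, one_window_grid(), resolution=50)
        assert ds.values[0, :, 0, 0].tolist() == [0, 0, 1, 0]

    def test_empty_alignment_gives_zero_tensor(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [])
        ds = coverage_from_bam(sam, one_window_grid(), resolution=50)
        assert ds.values.sum() == 0

    def test_stranded_channels_split_by_read_orientation(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [("chr1", 10, 20, False), ("chr1", 10, 20, True)])
        ds = coverage_from_bam(sam, one_window_grid(), resolution=200, stranded=True)
        assert ds.values[0, 0].tolist() == [[1.0], [1.0]]
        unstranded = coverage_from_bam(sam, one_window_grid(), resolution=200)
        assert unstranded.values[0, 0, 0, 0] == 2.0

    def test_mapq_filter_drops_reads(self, tmp_path):
        sam = tmp_path / "a.sam"
        lines = ["@HD\tVN:1.6", "@SQ\tSN:chr1\tLN:1000",
                 "r0\t0\tchr1\t11\t5\t20M\t*\t0\t0\t" + "A" * 20 + "\t*"]
        sam.write_text("\n".join(lines) + "\n")
        assert coverage_from_bam(sam, one_window_grid(), 200, min_mapq=30).values.sum() == 0
        assert coverage_from_bam(sam, one_window_grid(), 200, min_mapq=0).values.sum() == 1

    def test_matches_five_prime_oracle_pileup(self, sam_reads, grid):
        """Tensor equals a brute-force pileup of the generator's 5' ends."""
        sam_path, five_primes = sam_reads
        ds = coverage_from_bam(sam_path, grid, resolution=50, stranded=True)
        expect = np.zeros(ds.shape)
        for wi in range(len(grid)):
            chrom, fs, fe = grid.fetch_range(wi)
            for rc, rp, rstrand in five_primes:
                if rc == chrom and fs <= rp < fe:
                    expect[wi, (rp - fs) // 50, 0 if rstrand == "+" else 1, 0] += 1
        assert np.array_equal(ds.values, expect)

    def test_total_count_conservation_on_whole_genome_tiling(self, sam_reads, genome):
        sam_path, five_primes = sam_reads
        whole = RegionSet(
            [GenomicInterval(c, 0, genome.sizes[c] // 200 * 200) for c in genome.sizes],
            genome.sizes,
        )
        g = tile(whole, 200, 200, flank=0)
        ds = coverage_from_bam(sam_path, g, resolution=200)
        assert ds.values.sum() == len(five_primes)

    def test_resolution_must_divide_window(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [])
        with pytest.raises(ValueError, match="resolution"):
            coverage_from_bam(sam, one_window_grid(), resolution=60)

    def test_bam_input_equivalent_to_sam(self, tmp_path):
        import pysam

        sam = tmp_path / "a.sam"
        write_sam(sam, [("chr1", 10, 50, False), ("chr1", 100, 50, True)])
        bam = tmp_path / "a.bam"
        pysam.sort("-o", str(bam), str(sam))
        pysam.index(str(bam))
        a = coverage_from_bam(sam, one_window_grid(), 50)
        b = coverage_from_bam(bam, one_window_grid(), 50)
        assert np.array_equal(a.values, b.values)


class TestCoverageFromTracks:
    def test_constant_block_sum_and_mean(self, tmp_path):
        bg = tmp_path / "t.bedgraph"
        bg.write_text("chr1\t0\t100\t2.0\n")
        grid = one_window_grid(binsize=100)
        s = coverage_from_bigwig(bg, grid, resolution=50, agg="sum")
        assert s.values[0, :, 0, 0].tolist() == [100.0, 100.0]
        m = coverage_from_bigwig(bg, grid, resolution=50, agg="mean")
        assert m.values[0, :, 0, 0].tolist() == [2.0, 2.0]

    def test_gap_reads_as_zero(self, tmp_path):
        bg = tmp_path / "t.bedgraph"
        bg.write_text("chr1\t150\t200\t4.0\n")
        ds = coverage_from_bigwig(bg, one_window_grid(), resolution=50, agg="mean")
        assert ds.values[0, :, 0, 0].tolist() == [0.0, 0.0, 0.0, 4.0]

    def test_bigwig_binary_matches_bedgraph_text(self, tmp_path):
        pyBigWig = pytest.importorskip("pyBigWig")
        bg = tmp_path / "t.bedgraph"
        bg.write_text("chr1\t20\t120\t1.5\nchr1\t150\t180\t3.0\n")
        bw_path = tmp_path / "t.bw"
        bw = pyBigWig.open(str(bw_path), "w")
        bw.addHeader([("chr1", 1000)])
        bw.addEntries(["chr1", "chr1"], [20, 150], ends=[120, 180], values=[1.5, 3.0])
        bw.close()
        grid = one_window_grid()
        a = coverage_from_bigwig(bg, grid, resolution=50)
        b = coverage_from_bigwig(bw_path, grid, resolution=50)
        assert np.allclose(a.values, b.values)

    def test_unknown_chromosome_in_grid_rejected(self, tmp_path):
        bg = tmp_path / "t.bedgraph"
        bg.write_text("chr1\t0\t10\t1.0\n")
        other = ChromSizes({"chrZ": 500})
        grid = tile(RegionSet([GenomicInterval("chrZ", 0, 200)], other), 200, 200)
        # grid.sizes knows chrZ; but a grid chrom absent from the sizes mapping
        # cannot be constructed, so the error surfaces on sizes lookup of a
        # foreign-sizes grid
        grid.sizes = ChromSizes({"chr1": 1000})
        with pytest.raises(KeyError, match="chrZ"):
            coverage_from_bigwig(bg, grid, resolution=50)


class TestCoverageFromBed:
    def test_binary_mode_marks_any_overlap(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t150\t160\n")
        ds = coverage_from_bed(bed, one_window_grid(), resolution=200, mode="binary")
        assert ds.values[0, 0, 0, 0] == 1.0

    def test_no_overlap_is_zero(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t500\t600\n")
        ds = coverage_from_bed(bed, one_window_grid(), resolution=200, mode="binary")
        assert ds.values.sum() == 0

    def test_count_mode_counts_records(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t10\t60\nchr1\t40\t90\n")
        ds = coverage_from_bed(bed, one_window_grid(), resolution=200, mode="count")
        assert ds.values[0, 0, 0, 0] == 2.0

    def test_score_mode_takes_max_and_rejects_bed3(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t10\t60\ta\t5\t+\nchr1\t40\t90\tb\t9\t+\n")
        ds = coverage_from_bed(bed, one_window_grid(), resolution=200, mode="score")
        assert ds.values[0, 0, 0, 0] == 9.0
        bed3 = tmp_path / "q.bed"
        bed3.write_text("chr1\t10\t60\n")
        with pytest.raises(ValueError, match="score"):
            coverage_from_bed(bed3, one_window_grid(), resolution=200, mode="score")

    def test_binary_agrees_with_label_by_overlap(self, data_dir, genome, grid):
        peaks_path = data_dir / "peaks.narrowPeak"
        from seqcover.intervals import read_regions

        peaks = read_regions(peaks_path, "narrowpeak", genome.sizes)
        flat = tile(grid.source, grid.binsize, grid.stepsize, flank=0)
        ds = coverage_from_bed(peaks_path, flat, resolution=flat.binsize, mode="binary")
        assert np.array_equal(
            ds.values[:, 0, 0, 0].astype(int), label_by_overlap(flat, peaks)
        )


class TestShapesAndAggregation:
    def test_dnase_style_window_has_22_bins(self, roi):
        """200-bp bins with a 450-bp flank at 50-bp resolution span 1100 bp."""
        g = tile(roi, 200, 200, flank=450)
        assert g.window_length == 1100
        values = np.zeros((len(g), 22))
        ds = CoverageDataset.from_values(values, g, resolution=50)
        assert ds.bins_per_window == 22

    def test_indivisible_resolution_rejected(self, roi):
        g = tile(roi, 200, 200, flank=450)
        with pytest.raises(ValueError):
            CoverageDataset.from_values(np.zeros((len(g), 10)), g, resolution=100)

    def test_aggregate_sum_mean_max(self, rng):
        g = one_window_grid()
        ds = CoverageDataset.from_values(np.array([[1.0, 2.0, 3.0, 6.0]]), g, 50)
        assert aggregate_windows(ds, "sum")[0, 0] == 12.0
        assert aggregate_windows(ds, "mean")[0, 0] == 3.0
        assert aggregate_windows(ds, "max")[0, 0] == 6.0
        v = rng.random((5, 4, 2, 3))
        g5 = tile(RegionSet([GenomicInterval("chr1", 0, 1000)], SIZES), 200, 200)
        ds = CoverageDataset.from_values(v.reshape(5, 4, 2, 3)[:, :, 0, :], g5, 50)
        loop = np.array(
            [[ds.values[w, :, :, c].sum() for c in range(3)] for w in range(5)]
        )
        assert np.allclose(aggregate_windows(ds, "sum"), loop)


class TestBackends:
    @pytest.mark.parametrize("storage", ["ndarray", "sparse", "hdf5"])
    def test_identical_values_across_backends(self, sam_reads, grid, tmp_path, storage):
        sam_path, _ = sam_reads
        kwargs = {"storage": storage}
        if storage == "hdf5":
            kwargs["storage_path"] = tmp_path / "cov.h5"
        ds = coverage_from_bam(sam_path, grid, resolution=50, stranded=True, **kwargs)
        dense = coverage_from_bam(sam_path, grid, resolution=50, stranded=True)
        assert np.array_equal(ds.values, dense.values)
        assert ds.backend.kind == {"ndarray": "ndarray", "sparse": "sparse", "hdf5": "hdf5"}[storage]


class TestCache:
    def test_hit_skips_builder(self, sam_reads, grid, tmp_path):
        sam_path, _ = sam_reads
        calls = []

        def builder():
            calls.append(1)
            return coverage_from_bam(sam_path, grid, resolution=50)

        key = CacheKey.build([sam_path], {"resolution": 50})
        a = load_or_build(key, builder, tmp_path / "cache")
        b = load_or_build(key, builder, tmp_path / "cache")
        assert calls == [1]
        assert np.array_equal(a.values, b.values)

    def test_content_change_invalidates(self, tmp_path, sam_reads, grid):
        sam_path, _ = sam_reads
        src = tmp_path / "x.txt"
        src.write_text("aaa")
        calls = []

        def builder():
            calls.append(1)
            return coverage_from_bam(sam_path, grid, resolution=50)

        k1 = CacheKey.build([src], {"r": 50}, content_hash=True)
        load_or_build(k1, builder, tmp_path / "cache")
        src.write_text("bbb")
        k2 = CacheKey.build([src], {"r": 50}, content_hash=True)
        assert k1 != k2
        load_or_build(k2, builder, tmp_path / "cache")
        assert calls == [1, 1]

    def test_parameter_change_invalidates(self, tmp_path):
        src = tmp_path / "x.txt"
        src.write_text("aaa")
        k50 = CacheKey.build([src], {"resolution": 50})
        k25 = CacheKey.build([src], {"resolution": 25})
        assert k50 != k25

    def test_corrupt_entry_rebuilt(self, sam_reads, grid, tmp_path):
        sam_path, _ = sam_reads
        key = CacheKey.build([sam_path], {"resolution": 50})
        cache = tmp_path / "cache"
        cache.mkdir()
        (cache / f"{key.digest}.h5").write_text("not hdf5")
        ds = load_or_build(
            key, lambda: coverage_from_bam(sam_path, grid, resolution=50), cache
        )
        assert ds.values.sum() > 0
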