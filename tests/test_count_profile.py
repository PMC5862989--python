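"""Read ingestion, filtering, deduplication, counting, NDR and QC stats."""

import numpy as np
import pytest

import scwga_eval as sw
from scwga_eval import io as sio
from scwga_eval.count_profile import (AlignedRead, AlignmentStats, IngestStats,
                                      alignment_stats, compute_ndr,
                                      count_in_windows, dedupe_by_position,
                                      downsample, filter_reads,
                                      load_alignments)


def read(chrom="chr1", pos=100, strand="+", length=49, cigar=None, mm=0):
    return AlignedRead(chrom=chrom, pos=pos, strand=strand,
                       cigar=cigar or f"{length}M", read_length=length,
                       n_mismatch=mm)


class TestLoadAlignments:
    def test_sam_drops_unmapped_and_secondary(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.4\n@SQ\tSN:chr1\tLN:10000\n"
            "r0\t0\tchr1\t100\t60\t49M\t*\t0\t0\t*\t*\tNM:i:1\n"
            "r1\t16\tchr1\t200\t60\t49M\t*\t0\t0\t*\t*\tNM:i:0\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"          # unmapped
            "r3\t256\tchr1\t300\t0\t49M\t*\t0\t0\t*\t*\n"  # secondary
            "r4\t0\tchr1\t400\t60\t20M1I20M1D8M\t*\t0\t0\t*\t*\tNM:i:3\n"
        )
        stats = IngestStats()
        reads = list(load_alignments(sam, "sam", stats=stats))
        assert len(reads) == 3
        assert stats.total == 5 and stats.unmapped == 1 and stats.secondary == 1
        assert reads[0].n_mismatch == 1
        assert reads[1].strand == "-"
        assert reads[2].n_mismatch == 1  # NM 3 minus 1 ins minus 1 del

    def test_bed_roundtrip_of_simulated_reads(self, tmp_path, small_windows,
                                              diploid_truth, flat_kit):
        counts = sw.simulate_window_counts(small_windows, diploid_truth,
                                           flat_kit, 1, 5000, seed=2)
        reads = sw.simulate_alignments(small_windows, counts, flat_kit, seed=2)
        path = tmp_path / "reads.bed"
        sio.write_reads_bed(reads, path)
        back = list(load_alignments(path, "bed"))
        assert len(back) == len(reads)
        assert [(r.chrom, r.pos, r.strand) for r in back] == \
               [(r.chrom, r.pos, r.strand) for r in reads]

    def test_sam_roundtrip(self, tmp_path, small_genome, small_windows,
                           diploid_truth, flat_kit):
        counts = sw.simulate_window_counts(small_windows, diploid_truth,
                                           flat_kit, 1, 2000, seed=3)
        reads = sw.simulate_alignments(small_windows, counts, flat_kit, seed=3)
        path = tmp_path / "reads.sam"
        sio.write_sam(reads, small_genome.lengths, path)
        back = list(load_alignments(path, "sam"))
        assert [(r.chrom, r.pos, r.strand, r.cigar) for r in back] == \
               [(r.chrom, r.pos, r.strand, r.cigar) for r in reads]

    def test_malformed_bed_reports_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t59\t49M:0\t60\t+\nchr1\toops\n")
        with pytest.raises(ValueError, match="bad.bed:2"):
            list(load_alignments(p, "bed"))


class TestFilterReads:
    def test_strict_length_floor(self):
        reads = [read(length=n) for n in (25, 30, 31, 49)]
        kept = list(filter_reads(reads, 30, "variable"))
        assert [r.read_length for r in kept] == [31, 49]

    def test_length_30_dropped(self):
        assert list(filter_reads([read(length=30)], 30, "variable")) == []

    def test_zero_floor_is_identity(self):
        reads = [read(length=n) for n in (25, 49)]
        assert list(filter_reads(reads, 0, "variable")) == reads

    def test_fixed_dialect_passthrough(self):
        reads = [read(length=25)]
        assert list(filter_reads(reads, 30, "fixed-49")) == reads


class TestDedupe:
    def test_same_key_removed(self):
        res = dedupe_by_position([read(pos=5), read(pos=5)])
        assert len(res.reads) == 1
        assert res.duplication_rate == 50.0

    def test_opposite_strands_kept(self):
        res = dedupe_by_position([read(pos=5, strand="+"),
                                  read(pos=5, strand="-")])
        assert len(res.reads) == 2

    def test_pos_only_key(self):
        res = dedupe_by_position([read(pos=5, strand="+"),
                                  read(pos=5, strand="-")], key="pos")
        assert len(res.reads) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        reads = [read(pos=int(p)) for p in rng.integers(1, 200, 500)]
        once = dedupe_by_position(reads)
        twice = dedupe_by_position(once.reads)
        assert twice.n_removed == 0
        assert twice.reads == once.reads

    def test_first_seen_kept(self):
        a, b = read(pos=5, mm=0), read(pos=5, mm=7)
        assert dedupe_by_position([a, b]).reads == [a]


class TestDownsample:
    def test_identity_and_empty(self):
        reads = [read(pos=p) for p in range(1, 50)]
        assert downsample(reads, 100, seed=1) == reads
        assert downsample(reads, 0, seed=1) == []

    def test_deterministic(self):
        reads = [read(pos=p) for p in range(1, 1000)]
        assert downsample(reads, 100, seed=3) == downsample(reads, 100, seed=3)

    def test_preserves_stream_order(self):
        reads = [read(pos=p) for p in range(1, 1000)]
        out = downsample(reads, 100, seed=4)
        positions = [r.pos for r in out]
        assert positions == sorted(positions)

    def test_inclusion_uniformity(self):
        n_total, n_keep, n_seeds = 10_000, 1000, 200
        reads = [read(pos=p) for p in range(1, n_total + 1)]
        freq = np.zeros(n_total)
        for seed in range(n_seeds):
            for r in downsample(reads, n_keep, seed=seed):
                freq[r.pos - 1] += 1
        p = n_keep / n_total
        se = np.sqrt(p * (1 - p) / n_seeds)
        # per-read inclusion frequency within 4-sigma binomial band (allow
        # the expected handful of boundary cases among 10^4 reads)
        outside = np.abs(freq / n_seeds - p) > 4 * se
        assert outside.mean() < 0.002
        assert abs(freq.mean() / n_seeds - p) < 3 * se / np.sqrt(n_total) * 10


class TestCountInWindows:
    def test_single_read_single_window(self, small_windows):
        r = read(chrom=small_windows.chrom[3],
                 pos=int(small_windows.start[3]) + 30 + 1)
        wc = count_in_windows([r], small_windows)
        # position may sit in the overlap zone; window 3 must be hit
        assert wc.counts[3] >= 1
        assert wc.counts.sum() in (1, 2)

    def test_overlap_zone_double_counts(self, small_windows):
        i = 1
        shared = int(small_windows.start[i])  # first start of window i,
        # inside the 20-read overlap with window i-1
        assert shared <= small_windows.start_last[i - 1]
        r = read(chrom=small_windows.chrom[i], pos=shared + 1)
        wc = count_in_windows([r], small_windows)
        assert wc.counts[i - 1] == 1 and wc.counts[i] == 1

    def test_single_assignment_mode(self, small_windows):
        i = 1
        r = read(chrom=small_windows.chrom[i],
                 pos=int(small_windows.start[i]) + 1)
        wc = count_in_windows([r], small_windows, double_count_overlap=False)
        assert wc.counts.sum() == 1

    def test_matches_interval_scan_oracle(self, small_windows):
        rng = np.random.default_rng(8)
        reads = [read(chrom=rng.choice(["chr1", "chr2"]),
                      pos=int(rng.integers(1, 55_000)))
                 for _ in range(2000)]
        wc = count_in_windows(reads, small_windows)
        oracle = np.zeros(small_windows.n_windows, dtype=int)
        for r in reads:  # brute-force per-read interval scan
            for i in range(small_windows.n_windows):
                if (small_windows.chrom[i] == r.chrom
                        and small_windows.start[i] <= r.start0
                        <= small_windows.start_last[i]):
                    oracle[i] += 1
        assert np.array_equal(wc.counts, oracle)

    def test_unassigned_counted(self, small_windows):
        r = read(chrom="chrZ", pos=10)
        wc = count_in_windows([r], small_windows)
        assert wc.n_unassigned == 1

    def test_total_conserved_without_overlap(self):
        track = {"chr1": np.ones(2000, dtype=bool)}
        ws = sw.build_windows(track, reads_per_window=100, overlap_reads=0,
                              read_length=50, step=1)
        rng = np.random.default_rng(3)
        reads = [read(pos=int(p) + 1) for p in rng.integers(0, 2000, 500)]
        wc = count_in_windows(reads, ws)
        assert wc.counts.sum() == 500
        assert wc.n_unassigned == 0


class TestNDR:
    def make_counts(self, values, chroms=None):
        n = len(values)
        ws = sw.WindowSet.from_gc(np.full(n, 0.4),
                                  chrom=chroms if chroms is not None else "chr1")
        return sw.WindowCounts(windows=ws, counts=np.asarray(values))

    def test_equal_counts_all_one(self):
        ndr = compute_ndr(self.make_counts([7] * 12)).ndr
        assert np.all(ndr == 1.0)

    def test_simple_arithmetic(self):
        ndr = compute_ndr(self.make_counts([2, 4, 6])).ndr
        assert np.allclose(ndr, [0.5, 1.0, 1.5])

    def test_sex_windows_float_free(self):
        chroms = np.array(["chr1"] * 4 + ["chrX"] * 2, dtype=object)
        counts = self.make_counts([10, 20, 30, 40, 5, 100], chroms=chroms)
        prof = compute_ndr(counts)
        M = (10 + 20 + 30 + 40) / 4  # hand-recomputed autosomal mean
        assert np.allclose(prof.ndr, np.array([10, 20, 30, 40, 5, 100]) / M)
        assert prof.ndr[prof.autosomal_usable].mean() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        a = compute_ndr(self.make_counts([3, 5, 9, 11])).ndr
        b = compute_ndr(self.make_counts([30, 50, 90, 110])).ndr
        assert np.allclose(a, b)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty profile"):
            compute_ndr(self.make_counts([0, 0, 0]))


class TestAlignmentStats:
    def test_clean_cigar_zero_error(self):
        stats = alignment_stats([], [read(cigar="50M", mm=0, length=50)])
        assert stats.error_rate == 0.0

    def test_hand_counted_rates(self):
        # 100 aligned (M) bases total, 2 mismatches, 1 deletion, 1 insertion
        r1 = read(cigar="50M", mm=2, length=50)
        r2 = read(cigar="25M1I24M1D1M", mm=0, length=50)
        stats = alignment_stats([], [r1, r2])
        assert stats.mismatch_rate == pytest.approx(2.0)
        assert stats.deletion_rate == pytest.approx(1.0)
        assert stats.insertion_rate == pytest.approx(1.0)
        assert stats.error_rate == pytest.approx(4.0)

    def test_error_rate_is_exact_sum_of_printed_components(self):
        stats = AlignmentStats.from_component_rates(1.76, 0.03, 0.02)
        assert stats.error_rate == pytest.approx(1.81, abs=1e-12)

    def test_unknown_mismatches_reported_unavailable(self):
        r = read(cigar="50M", length=50)
        r.n_mismatch = None
        stats = alignment_stats([], [r])
        assert stats.mismatch_rate is None
        assert stats.error_rate is None
        assert stats.deletion_rate == 0.0

    def test_coverage_union(self):
        reads = [read(pos=1, cigar="50M", length=50),
                 read(pos=26, cigar="50M", length=50),   # overlaps the first
                 read(pos=201, cigar="50M", length=50)]
        stats = alignment_stats([], reads, genome_length=1000)
        assert stats.coverage == pytest.approx(100 * (75 + 50) / 1000)

    def test_malformed_cigar_skipped(self):
        bad = read(cigar="12Q", length=12)
        stats = alignment_stats([], [bad, read(cigar="50M", length=50)])
        assert stats.n_skipped == 1
        assert stats.n_reads == 2
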