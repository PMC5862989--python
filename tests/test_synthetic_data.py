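"""Generator correctness: GC landscape, truth panels, count and read simulation."""

import numpy as np
import pytest

import scwga_eval as sw
from scwga_eval.count_profile import count_in_windows, dedupe_by_position


def windowed_gc(seq, size):
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    n = len(seq) // size
    return is_gc[: n * size].reshape(n, size).mean(axis=1)


class TestGenerateGenome:
    def test_zero_amplitude_gc_is_flat(self):
        g = sw.generate_genome(1, 100_000, sw.GCLandscape(0.42, 0.0, 1000), seed=1)
        gc = windowed_gc(g.sequence("chr1"), 1000)
        # per-window binomial noise: sd = sqrt(p(1-p)/1000) ~ 0.0156
        assert np.all(np.abs(gc - 0.42) < 5 * np.sqrt(0.42 * 0.58 / 1000))
        assert abs(gc.mean() - 0.42) < 0.005

    def test_seed_determinism(self):
        params = sw.GCLandscape(0.42, 0.15, 5000)
        a = sw.generate_genome(2, [200_000, 200_000], params, seed=7)
        b = sw.generate_genome(2, [200_000, 200_000], params, seed=7)
        assert a.chromosomes == b.chromosomes
        c = sw.generate_genome(2, [200_000, 200_000], params, seed=8)
        assert c.chromosomes != a.chromosomes

    def test_gc_span_covers_amplitude(self):
        g = sw.generate_genome(1, 500_000, sw.GCLandscape(0.42, 0.1, 10_000), seed=3)
        gc = windowed_gc(g.sequence("chr1"), 1000)
        assert gc.min() <= 0.32 and gc.max() >= 0.52

    def test_gc_autocorrelation_decays_with_distance(self):
        g = sw.generate_genome(1, 500_000,
                               sw.GCLandscape(0.42, 0.15, 10_000), seed=3)
        gc = windowed_gc(g.sequence("chr1"), 1000)
        # brute-force lag autocorrelation oracle
        def acf(x, lag):
            a, b = x[:-lag], x[lag:]
            return np.mean((a - a.mean()) * (b - b.mean())) / (x.std() ** 2)

        short, mid, far = acf(gc, 2), acf(gc, 15), acf(gc, 150)
        assert short > mid > far
        assert short > 0.5
        assert abs(far) < 0.35

    def test_rejects_bad_lengths(self):
        with pytest.raises(ValueError, match="positive"):
            sw.generate_genome(1, [-5])
        with pytest.raises(ValueError):
            sw.generate_genome(0, [])


class TestTruthProfiles:
    def test_default_panel_shape(self, small_genome):
        profiles = sw.generate_truth_profiles(small_genome, seed=2)
        assert len(profiles) == 11
        assert sum(p.label == "negative" for p in profiles) == 1
        assert sum(p.label == "aneuploid" for p in profiles) == 1
        n_cnvs = sum(len(p.positive_segments) for p in profiles
                     if p.label == "cnv")
        assert n_cnvs == 10

    def test_empty_spec(self, small_genome):
        assert sw.generate_truth_profiles(small_genome, spec=[]) == []

    def test_copy_number_point_lookup(self, small_genome):
        spec = [("cnv", [("chr1", 10_000, 15_000, 1)])]
        (p,) = sw.generate_truth_profiles(small_genome, spec=spec)
        assert p.copy_number("chr1", 10_000) == 1
        assert p.copy_number("chr1", 14_999) == 1
        assert p.copy_number("chr1", 15_000) == 2
        assert p.copy_number("chr1", 9_999) == 2
        assert p.copy_number("chr2", 12_000) == 2

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sw.TruthProfile("X", (("chr1", 0, 100, 3), ("chr1", 50, 200, 1)))

    def test_out_of_bounds_rejected(self, small_genome):
        with pytest.raises(ValueError, match="exceeds"):
            sw.generate_truth_profiles(
                small_genome, spec=[("cnv", [("chr1", 0, 10 ** 9, 3)])])


class TestSimulateWindowCounts:
    def test_poisson_limit_cv(self, diploid_truth, flat_kit):
        n = 100_000
        ws = sw.WindowSet.from_gc(np.full(n, 0.4))
        mean = 30
        c = sw.simulate_window_counts(ws, diploid_truth, flat_kit, 1,
                                      n * mean, seed=5)
        ndr = c.counts / c.counts.mean()
        cv = ndr.std()
        expect = 1 / np.sqrt(mean)
        # MC standard error of the CV for Poisson data
        se = expect / np.sqrt(2 * n)
        assert abs(cv - expect) < 4 * se

    def test_count_conservation(self, small_windows, diploid_truth):
        kit = sw.picoplex_like_kit()
        mu = sw.expected_window_counts(small_windows, diploid_truth, kit, 500_000)
        assert abs(mu.sum() - 500_000) < 0.001 * 500_000

    def test_copy3_ratio_noise_free(self, diploid_truth, flat_kit):
        n = 1000
        ws = sw.WindowSet.from_gc(np.full(n, 0.4))
        half = int(ws.end[n // 2 - 1])
        truth = sw.TruthProfile("T", (("chr1", 0, half, 3),), label="cnv")
        c = sw.simulate_window_counts(ws, truth, flat_kit, 1, 600_000,
                                      seed=1, noise="none")
        inside = c.counts[: n // 2].mean()
        outside = c.counts[n // 2:].mean()
        assert inside / outside == pytest.approx(1.5, rel=1e-3)

    def test_ndr_equals_half_copy_number_without_noise(self, flat_kit):
        ws = sw.WindowSet.from_gc(np.full(400, 0.45))
        truth = sw.TruthProfile(
            "T", (("chr1", 0, int(ws.end[99]), 1),), label="cnv")
        c = sw.simulate_window_counts(ws, truth, flat_kit, 1, 350_000,
                                      seed=0, noise="none")
        ndr = sw.compute_ndr(c).ndr
        cn = truth.copy_number_at(ws.chrom, (ws.start + ws.end) // 2)
        # with zero dispersion and flat efficiency NDR is proportional to
        # copy/2 exactly (the autosomal mean, deletion included, is 1)
        scaled = ndr / (cn / 2)
        assert np.ptp(scaled) < 0.01
        assert ndr[:100].mean() / ndr[100:].mean() == pytest.approx(0.5, abs=0.005)

    def test_gc_bias_monotone_in_amplitude(self, diploid_truth):
        n = 3000
        rng = np.random.default_rng(0)
        ws = sw.WindowSet.from_gc(rng.uniform(0.3, 0.6, n))
        deltas = {amp: [] for amp in (0.0, 0.8, 2.0)}
        for amp in deltas:
            kit = sw.KitProfile(
                name="k", gc_efficiency=sw.quadratic_efficiency(amp, 0.0, 0.45),
                dispersion_single=0.05, dispersion_multi=0.05,
                duplication_rate=0.0)
            for seed in range(5):
                c = sw.simulate_window_counts(ws, diploid_truth, kit, 1,
                                              n * 100, seed=seed)
                deltas[amp].append(sw.delta_r_gc(c).delta_r_gc)
        m0, m1, m2 = (np.mean(deltas[a]) for a in (0.0, 0.8, 2.0))
        assert m0 < m1 < m2
        assert m0 < 0.05
        assert m2 > 0.3

    def test_seed_determinism(self, small_windows, diploid_truth):
        kit = sw.wga4_like_kit()
        a = sw.simulate_window_counts(small_windows, diploid_truth, kit, 1,
                                      100_000, seed=9)
        b = sw.simulate_window_counts(small_windows, diploid_truth, kit, 1,
                                      100_000, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_undefined_gc_rejected(self, diploid_truth, flat_kit):
        ws = sw.WindowSet.from_gc([0.4, np.nan, 0.5])
        with pytest.raises(ValueError, match="undefined GC"):
            sw.simulate_window_counts(ws, diploid_truth, flat_kit, 1, 1000)


@pytest.fixture(scope="module")
def counts(small_windows, diploid_truth, flat_kit):
    return sw.simulate_window_counts(small_windows, diploid_truth,
                                     flat_kit, 1, 20_000, seed=4)


class TestSimulateAlignments:

    def test_no_duplicates_when_rate_zero(self, small_windows, counts, flat_kit):
        reads = sw.simulate_alignments(small_windows, counts, flat_kit, seed=1)
        res = dedupe_by_position(reads)
        assert res.n_removed == 0

    def test_duplicate_rate_recovered(self, small_windows, counts):
        kit = sw.KitProfile(name="dup", gc_efficiency=sw.flat_efficiency(),
                            dispersion_single=0.0, dispersion_multi=0.0,
                            duplication_rate=0.2, error_rates=(0, 0, 0))
        reads = sw.simulate_alignments(small_windows, counts, kit, seed=2)
        res = dedupe_by_position(reads)
        n_injected = sum(r.is_duplicate for r in reads)
        assert res.n_removed == n_injected  # simulator bookkeeping, exact
        rate = res.n_removed / res.n_input
        se = np.sqrt(0.2 * 0.8 / len(reads))
        assert abs(rate - 0.2) < 5 * se

    def test_recounting_reproduces_counts(self, small_windows, counts):
        kit = sw.KitProfile(name="dup", gc_efficiency=sw.flat_efficiency(),
                            dispersion_single=0.0, dispersion_multi=0.0,
                            duplication_rate=0.1, error_rates=(0, 0, 0))
        reads = sw.simulate_alignments(small_windows, counts, kit, seed=3)
        dedup = dedupe_by_position(reads).reads
        recount = count_in_windows(dedup, small_windows)
        assert np.array_equal(recount.counts, counts.counts)

    def test_error_rates_recovered(self, small_windows, counts):
        kit = sw.KitProfile(name="err", gc_efficiency=sw.flat_efficiency(),
                            dispersion_single=0.0, dispersion_multi=0.0,
                            duplication_rate=0.0,
                            error_rates=(0.01, 0.003, 0.002))
        reads = []
        for seed in range(5):
            reads += sw.simulate_alignments(small_windows, counts, kit,
                                            read_length_mode="variable-min30",
                                            seed=seed)
        stats = sw.alignment_stats(reads, reads)
        n_bases = sum(r.read_length for r in reads)
        assert n_bases > 1e6
        for rate, expect in [(stats.mismatch_rate, 1.0),
                             (stats.deletion_rate, 0.3),
                             (stats.insertion_rate, 0.2)]:
            se = 100 * np.sqrt(expect / 100 / n_bases)
            assert abs(rate - expect) < 4 * se
        assert stats.error_rate == pytest.approx(
            stats.mismatch_rate + stats.deletion_rate + stats.insertion_rate)

    def test_fixed49_dialect(self, small_windows, counts, flat_kit):
        reads = sw.simulate_alignments(small_windows, counts, flat_kit,
                                       read_length_mode="fixed-49", seed=1)
        assert {r.read_length for r in reads} == {49}

    def test_variable_dialect_lengths(self, small_windows, counts, flat_kit):
        reads = sw.simulate_alignments(small_windows, counts, flat_kit,
                                       read_length_mode="variable-min30", seed=1)
        lens = np.array([r.read_length for r in reads])
        assert lens.min() >= 20 and lens.max() <= 200
        assert len(np.unique(lens)) > 20
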