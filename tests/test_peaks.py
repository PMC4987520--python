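"""Window/Poisson peak caller: unit behaviour and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcellkit.intervals import GenomicInterval
from bcellkit.peaks import (
    AlignedRead,
    EmptyLibraryError,
    PeakCallerConfig,
    WindowStats,
    call_peaks,
    count_windows,
    dedupe_reads,
    extend_read,
    flag_windows,
    merge_peaks,
    normalize_input,
    poisson_upper_tail,
)
from bcellkit.synth import SpikeDesign, make_toy_genome, simulate_chip_library
from oracles import call_peaks_naive, pmf_upper_tail


class TestDedupe:
    def test_empty_and_all_unique_pass_through(self):
        assert dedupe_reads([]) == []
        reads = [AlignedRead("chr1", p, "+", 50) for p in (10, 20, 30)]
        assert dedupe_reads(reads) == reads

    def test_key_is_chrom_position_strand(self):
        reads = [
            AlignedRead("chr1", 100, "+", 50),
            AlignedRead("chr1", 100, "+", 50),
            AlignedRead("chr1", 100, "-", 50),
        ]
        kept = dedupe_reads(reads)
        assert len(kept) == 2
        assert [r.strand for r in kept] == ["+", "-"]
        # strand-blind key collapses all three
        assert len(dedupe_reads(reads, stranded=False)) == 1


class TestExtendRead:
    def test_plus_strand_fragment(self):
        iv = extend_read(AlignedRead("chr1", 100, "+", 50), 150)
        assert (iv.start, iv.end) == (100, 250)

    def test_minus_strand_fragment_extends_leftward(self):
        iv = extend_read(AlignedRead("chr1", 400, "-", 50), 150)
        assert (iv.start, iv.end) == (300, 450)

    def test_clipping_at_chromosome_start(self):
        iv = extend_read(AlignedRead("chr1", 10, "-", 50), 150)
        assert (iv.start, iv.end) == (0, 60)

    def test_length_plus_mode_keeps_read_body(self):
        iv = extend_read(AlignedRead("chr1", 100, "+", 50), 150, mode="length_plus")
        assert (iv.start, iv.end) == (100, 300)

    def test_clipping_at_chromosome_end(self):
        iv = extend_read(AlignedRead("chr1", 900, "+", 50), 150, chrom_length=1000)
        assert (iv.start, iv.end) == (900, 1000)


class TestCountWindows:
    SIZES = {"chr1": 1_000}

    def test_fragment_spanning_three_windows(self):
        counts = count_windows([GenomicInterval("chr1", 100, 250)], self.SIZES)
        expected = np.zeros(20, dtype=int)
        expected[[2, 3, 4]] = 1
        assert np.array_equal(counts["chr1"], expected)

    def test_no_fragments_all_zero(self):
        counts = count_windows([], self.SIZES)
        assert counts["chr1"].sum() == 0 and len(counts["chr1"]) == 20

    def test_exact_tiling_hits_single_window(self):
        counts = count_windows([GenomicInterval("chr1", 0, 50)], self.SIZES)
        assert counts["chr1"][0] == 1 and counts["chr1"][1:].sum() == 0

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            count_windows([GenomicInterval("chrX", 0, 50)], self.SIZES)

    def test_total_assignments_equal_windows_overlapped(self):
        rng = np.random.default_rng(0)
        frags = [
            GenomicInterval("chr1", int(s), int(s) + 150)
            for s in rng.integers(0, 850, size=200)
        ]
        counts = count_windows(frags, self.SIZES)
        expected = sum(
            (f.end - 1) // 50 - f.start // 50 + 1 for f in frags
        )
        assert counts["chr1"].sum() == expected


class TestNormalizeInput:
    def test_scaling_arithmetic(self):
        assert normalize_input(1000, 500, 4, 0.0) == 8.0

    def test_equal_totals_identity(self):
        assert normalize_input(700, 700, 13, 0.0) == 13.0

    def test_floor_applies_to_zero_input_windows(self):
        assert normalize_input(1000, 1000, 0, 0.8) == 0.8

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            normalize_input(0, 500, 4)


class TestPoissonUpperTail:
    def test_whole_support_and_degenerate_cases(self):
        assert poisson_upper_tail(0, 5.0) == 1.0
        assert poisson_upper_tail(3, 0.0) == 0.0
        assert poisson_upper_tail(0, 0.0) == 1.0

    def test_matches_pmf_summation_oracle(self):
        assert poisson_upper_tail(5, 1.0) == pytest.approx(3.660e-3, rel=1e-3)
        for k in range(0, 30):
            for lam in (0.5, 1.0, 5.0, 20.0):
                assert poisson_upper_tail(k, lam) == pytest.approx(
                    pmf_upper_tail(k, lam), rel=1e-9, abs=1e-300
                )

    @given(
        k=st.integers(1, 200),
        lam=st.floats(0.01, 500.0),
        dlam=st.floats(0.01, 50.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_k_and_lambda(self, k, lam, dlam):
        assert poisson_upper_tail(k + 1, lam) <= poisson_upper_tail(k, lam)
        assert poisson_upper_tail(k, lam + dlam) >= poisson_upper_tail(k, lam)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(-1, 1.0)


def _stats_from_pvals(pvals, ip_counts=None):
    n = len(pvals)
    return WindowStats(
        chrom="chr1",
        window=50,
        chrom_length=50 * n,
        ip_count=np.asarray(ip_counts if ip_counts is not None else [1] * n),
        input_count=np.zeros(n, dtype=int),
        lam=np.ones(n),
        pval=np.asarray(pvals, dtype=float),
    )


class TestFlagWindows:
    def test_three_consecutive_rule(self):
        ws = _stats_from_pvals([0.5, 1e-4, 1e-4, 1e-4, 0.5])
        flag_windows([ws])
        assert list(ws.significant) == [False, True, True, True, False]
        assert list(ws.qualifying) == [False, False, True, False, False]

    def test_nothing_significant_nothing_qualifies(self):
        ws = _stats_from_pvals([1.0] * 5)
        flag_windows([ws])
        assert not ws.significant.any() and not ws.qualifying.any()

    def test_terminal_windows_never_qualify(self):
        ws = _stats_from_pvals([1e-4, 1e-4])
        flag_windows([ws])
        assert list(ws.significant) == [True, True]
        assert list(ws.qualifying) == [False, False]

    def test_threshold_is_strict(self):
        ws = _stats_from_pvals([1e-3, 0.999e-3])
        flag_windows([ws], alpha=1e-3)
        assert list(ws.significant) == [False, True]


class TestMergePeaks:
    def test_three_window_run_becomes_one_peak(self):
        ws = _stats_from_pvals([0.5, 1e-4, 1e-4, 1e-4, 0.5], ip_counts=[0, 3, 9, 4, 0])
        flag_windows([ws])
        peaks = merge_peaks([ws])
        assert len(peaks) == 1
        (pk,) = peaks
        assert (pk.interval.start, pk.interval.end) == (50, 200)
        assert pk.n_windows == 3
        assert pk.min_pval == pytest.approx(1e-4)
        assert pk.summit == 125  # midpoint of the max-count window [100,150)

    def test_run_of_two_yields_no_peak(self):
        ws = _stats_from_pvals([1e-4, 1e-4, 0.5, 0.5])
        flag_windows([ws])
        assert merge_peaks([ws]) == []

    def test_runs_split_by_gap_yield_separate_peaks(self):
        pvals = [1e-4] * 3 + [0.5] + [1e-4] * 3
        ws = _stats_from_pvals(pvals)
        flag_windows([ws])
        peaks = merge_peaks([ws])
        assert [(p.interval.start, p.interval.end) for p in peaks] == [
            (0, 150),
            (200, 350),
        ]


class TestCallPeaks:
    def test_identical_libraries_yield_no_peaks(self):
        genome = make_toy_genome(1, 50_000, 0, seed=1)
        design = SpikeDesign(depth=20_000)
        lib = simulate_chip_library(genome, design, is_input=True, seed=5)
        peaks, _ = call_peaks(lib, list(lib), genome.chrom_sizes)
        assert peaks == []

    def test_empty_library_error_names_the_library(self):
        genome = make_toy_genome(1, 50_000, 0, seed=1)
        lib = [AlignedRead("chr1", 100, "+", 50)]
        with pytest.raises(EmptyLibraryError, match="IP"):
            call_peaks([], lib, genome.chrom_sizes)
        with pytest.raises(EmptyLibraryError, match="input"):
            call_peaks(lib, [], genome.chrom_sizes)

    def test_single_spike_recovered_as_single_peak(self):
        genome = make_toy_genome(1, 100_000, 0, seed=1)
        spike = GenomicInterval("chr1", 40_000, 40_500)
        design = SpikeDesign(regions=(spike,), enrichment=(20.0,), depth=200_000)
        ip = simulate_chip_library(genome, design, is_input=False, seed=2)
        inp = simulate_chip_library(genome, design, is_input=True, seed=3)
        peaks, _ = call_peaks(ip, inp, genome.chrom_sizes)
        assert len(peaks) == 1
        assert peaks[0].interval.overlaps(spike)

    @pytest.mark.parametrize("seed", range(4))
    def test_equivalent_to_brute_force_reimplementation(self, seed):
        genome = make_toy_genome(2, 50_000, 0, seed=seed)
        regions = tuple(
            GenomicInterval("chr1", s, s + 400) for s in (5_000, 20_000)
        )
        design = SpikeDesign(regions=regions, enrichment=(8.0, 15.0), depth=30_000)
        ip = simulate_chip_library(genome, design, is_input=False, seed=seed * 2 + 100)
        inp = simulate_chip_library(genome, design, is_input=True, seed=seed * 2 + 101)
        peaks, _ = call_peaks(ip, inp, genome.chrom_sizes)
        got = [(p.interval.chrom, p.interval.start, p.interval.end) for p in peaks]
        assert got == call_peaks_naive(ip, inp, genome.chrom_sizes)

    def test_deterministic_pure_function(self):
        genome = make_toy_genome(1, 50_000, 0, seed=3)
        design = SpikeDesign(
            regions=(GenomicInterval("chr1", 10_000, 10_500),),
            enrichment=(10.0,),
            depth=50_000,
        )
        ip = simulate_chip_library(genome, design, is_input=False, seed=8)
        inp = simulate_chip_library(genome, design, is_input=True, seed=9)
        first, _ = call_peaks(ip, inp, genome.chrom_sizes)
        second, _ = call_peaks(list(ip), list(inp), genome.chrom_sizes)
        assert first == second
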