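"""Border caller: global median, binning, edge detection, consensus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hp1kit import (
    Genome,
    GenomicInterval,
    PeakSet,
    bin_profile,
    call_border,
    consensus_border,
    global_median_height,
)
from hp1kit.borders import BinProfile, BinnedProfile


def _landscape_from_bin_medians(medians, bin_size=500_000, chrom="chr2R"):
    """Three identical-height peaks per bin, so the bin median is exact."""
    genome = Genome({chrom: bin_size * len(medians)})
    ivs = []
    for i, m in enumerate(medians):
        for k in range(3):
            s = i * bin_size + 1000 * (k + 1)
            ivs.append(GenomicInterval(chrom, s - 10, s + 10, float(m), s))
    return PeakSet(ivs, genome)


def _profile_from(medians, direction="increasing", bin_size=500_000):
    """Profile whose bins, in scan order, have exactly these medians."""
    genomic = medians if direction == "increasing" else list(reversed(medians))
    ps = _landscape_from_bin_medians(genomic, bin_size)
    origin = 0 if direction == "increasing" else bin_size * len(medians)
    return bin_profile(ps, "chr2R", origin, direction, bin_size)


class TestGlobalMedian:
    @pytest.mark.parametrize(
        "heights, expected",
        [([1, 2, 3], 2.0), ([1, 2, 3, 10], 2.5), ([7.25], 7.25)],
    )
    def test_median_conventions(self, heights, expected):
        genome = Genome({"c": 10_000})
        ps = PeakSet(
            [
                GenomicInterval("c", 10 * i, 10 * i + 5, float(h))
                for i, h in enumerate(heights)
            ],
            genome,
        )
        assert global_median_height(ps) == expected

    def test_empty_or_heightless_rejected(self):
        genome = Genome({"c": 100})
        with pytest.raises(ValueError):
            global_median_height(PeakSet([], genome))
        ps = PeakSet([GenomicInterval("c", 0, 10)], genome)
        with pytest.raises(ValueError):
            global_median_height(ps)


class TestBinProfile:
    def _one_summit(self, summit, origin=0, direction="increasing"):
        genome = Genome({"c": 2_000_000})
        ps = PeakSet(
            [GenomicInterval("c", summit - 5, summit + 5, 1.0, summit)], genome
        )
        return bin_profile(ps, "c", origin, direction, 500_000)

    def test_summit_inside_first_bin(self):
        prof = self._one_summit(200_000)
        assert prof.bins[0].n_peaks == 1
        assert sum(b.n_peaks for b in prof.bins[1:]) == 0

    def test_summit_at_boundary_goes_to_higher_index_bin(self):
        prof = self._one_summit(500_000)
        assert prof.bins[0].n_peaks == 0
        assert prof.bins[1].n_peaks == 1

    def test_empty_bins_have_zero_median(self):
        genome = Genome({"c": 2_000_000, "other": 1_000_000})
        ps = PeakSet(
            [GenomicInterval("other", 0, 100, 5.0, 50)], genome
        )
        prof = bin_profile(ps, "c", 0, "increasing", 500_000)
        assert all(b.n_peaks == 0 and b.median_height == 0.0 for b in prof.bins)

    def test_bins_tile_the_scanned_range(self):
        prof = self._one_summit(100_000, origin=250_000)
        assert prof.bins[0].bin_start == 250_000
        assert prof.bins[-1].bin_end == 2_000_000
        for a, b in zip(prof.bins, prof.bins[1:]):
            assert a.bin_end == b.bin_start

    def test_decreasing_direction_scans_toward_zero(self):
        prof = self._one_summit(1_900_000, origin=2_000_000, direction="decreasing")
        assert prof.bins[0].n_peaks == 1
        assert prof.bins[0].bin_end == 2_000_000
        assert prof.bins[-1].bin_start == 0

    def test_midpoint_imputation_without_summits(self):
        genome = Genome({"c": 2_000_000})
        ps = PeakSet([GenomicInterval("c", 400_000, 700_000, 1.0)], genome)
        prof = bin_profile(ps, "c", 0, "increasing", 500_000)
        # midpoint 550,000 lands in bin 1
        assert prof.bins[1].n_peaks == 1

    def test_bad_bin_size_rejected(self):
        genome = Genome({"c": 1_000})
        ps = PeakSet([GenomicInterval("c", 0, 10, 1.0)], genome)
        with pytest.raises(ValueError):
            bin_profile(ps, "c", 0, "increasing", 0)


class TestCallBorder:
    def test_first_strict_drop_marks_the_edge(self):
        """The published decay pattern: ~3.1 a.u. near the chromocenter,
        then 1.4, then below the 0.9 global median."""
        prof = _profile_from([3.1, 3.0, 1.4, 0.5, 0.4])
        call = call_border(prof, global_median=0.9)
        assert call.border_pos == 1_500_000

    def test_equal_to_median_does_not_trigger(self):
        prof = _profile_from([3.0, 0.9, 0.8])
        call = call_border(prof, global_median=0.9)
        assert call.border_pos == 1_000_000  # the 0.8 bin, not the 0.9 bin

    def test_no_bin_below_median_gives_absent_border(self):
        prof = _profile_from([3.0, 2.0, 1.5])
        assert call_border(prof, global_median=0.9).border_pos is None

    def test_prefix_bins_all_at_or_above_median(self):
        prof = _profile_from([3.0, 1.0, 0.5, 2.0, 0.1])
        call = call_border(prof, global_median=0.9)
        idx = call.border_pos // 500_000
        assert all(
            b.median_height >= 0.9 for b in prof.bins[:idx]
        )

    def test_report_coordinate_variants(self):
        prof = _profile_from([3.0, 0.5])
        assert call_border(prof, 0.9, report="start").border_pos == 500_000
        assert call_border(prof, 0.9, report="end").border_pos == 1_000_000
        assert call_border(prof, 0.9, report="midpoint").border_pos == 750_000

    def test_min_run_skips_isolated_dips(self):
        prof = _profile_from([3.0, 0.5, 3.0, 0.5, 0.4, 0.3])
        assert call_border(prof, 0.9, min_run=1).border_pos == 500_000
        assert call_border(prof, 0.9, min_run=2).border_pos == 1_500_000

    def test_decreasing_direction_reports_origin_proximal_boundary(self):
        prof = _profile_from([3.0, 3.0, 0.5], direction="decreasing")
        # scanning from 1.5 Mb toward 0: third bin is [0, 0.5 Mb); its
        # origin-proximal boundary is 0.5 Mb
        assert call_border(prof, 0.9).border_pos == 500_000

    @given(
        medians=st.lists(
            st.floats(min_value=0.05, max_value=5.0, allow_nan=False),
            min_size=1,
            max_size=12,
        ),
        scale=st.sampled_from([0.25, 0.5, 2.0, 4.0, 16.0]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_equivariance(self, medians, scale):
        """Multiplying all heights by c > 0 leaves the border unchanged."""
        gm = float(np.median(medians))
        a = call_border(_profile_from(medians), gm)
        b = call_border(_profile_from([m * scale for m in medians]), gm * scale)
        assert a.border_pos == b.border_pos

    def test_invariant_to_peak_order(self):
        ps = _landscape_from_bin_medians([3.0, 1.4, 0.5])
        shuffled = PeakSet(list(ps.intervals)[::-1], ps.genome)
        gm = global_median_height(ps)
        a = call_border(bin_profile(ps, "chr2R", 0, "increasing"), gm)
        b = call_border(bin_profile(shuffled, "chr2R", 0, "increasing"), gm)
        assert a == b

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            call_border(
                BinnedProfile("c", 0, "increasing", 500_000, ()), 1.0
            )


class TestConsensusBorder:
    def _call(self, pos, chrom="chr2R", direction="increasing"):
        prof = BinnedProfile(chrom, 0, direction, 500_000, (
            BinProfile(0, 0, 500_000, 1, 3.0),
        ))
        from hp1kit.borders import BorderCall

        return BorderCall(chrom, pos, 0.9, 500_000, direction, prof)

    def test_identical_calls_agree(self):
        calls = [self._call(7_000_000)] * 3
        c = consensus_border(calls, tolerance=500_000)
        assert c.agreement and c.consensus_pos == 7_000_000

    def test_within_tolerance_agrees(self):
        # two tracks calling 7.3 vs 7.4 Mb with 0.5 Mb tolerance
        c = consensus_border(
            [self._call(7_300_000), self._call(7_400_000)], tolerance=500_000
        )
        assert c.agreement and c.consensus_pos == 7_350_000

    def test_absent_border_breaks_agreement(self):
        c = consensus_border(
            [self._call(7_000_000), self._call(None)], tolerance=500_000
        )
        assert not c.agreement and c.consensus_pos is None

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            consensus_border(
                [self._call(1), self._call(1, chrom="chrX")], tolerance=1
            )

    def test_fewer_than_two_calls_rejected(self):
        with pytest.raises(ValueError):
            consensus_border([self._call(1)], tolerance=1)
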