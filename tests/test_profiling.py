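"""End profiling: size partition, nucleosome-relative histograms, peaks."""

import numpy as np
import pytest

import fragaxis as fx
from fragaxis.profiling import EndPeakSet


@pytest.fixture(scope="module")
def short_long(control_pool):
    return fx.partition_by_size(control_pool)


@pytest.fixture(scope="module")
def short_profile(short_long, track):
    return fx.relative_end_profile(short_long.short, track)


class TestPartition:
    def test_threshold_boundaries(self):
        fs = fx.FragmentSet(
            "s", "chrS", [0, 0, 0], [147, 148, 170]
        )
        part = fx.partition_by_size(fs)
        assert list(part.short.sizes) == [147]
        assert list(part.middle.sizes) == [148]
        assert list(part.long.sizes) == [170]

    def test_empty_input(self):
        fs = fx.FragmentSet("s", "chrS", np.empty(0, int), np.empty(0, int))
        part = fx.partition_by_size(fs)
        assert len(part.short) == len(part.middle) == len(part.long) == 0

    def test_partition_covers_input(self, control_pool, short_long):
        total = len(short_long.short) + len(short_long.middle) + len(short_long.long)
        assert total == len(control_pool)

    def test_bad_thresholds_rejected(self, control_pool):
        with pytest.raises(ValueError):
            fx.partition_by_size(control_pool, short_max=170, long_min=147)


class TestRelativeProfile:
    def test_single_fragment_end_positions(self, track):
        _, centers = track.single_chrom()
        c = int(centers[5])
        fs = fx.FragmentSet("s", "chrS", [c - 68], [c + 75])
        profile = fx.relative_end_profile(fs, track)
        assert profile.u_counts[profile.positions == -68] == 1
        assert profile.d_counts[profile.positions == 74] == 1
        assert profile.total_assigned == 2

    def test_far_fragment_unassigned(self, track):
        _, centers = track.single_chrom()
        far = int(centers[-1]) + 5000
        fs = fx.FragmentSet("s", "chrS", [far], [far + 100])
        profile = fx.relative_end_profile(fs, track)
        assert profile.total_assigned == 0
        assert profile.unassigned_u == 1 and profile.unassigned_d == 1

    def test_end_assignment_conservation(self, control_pool, track):
        profile = fx.relative_end_profile(control_pool, track)
        assert (
            profile.total_assigned + profile.unassigned_u + profile.unassigned_d
            == 2 * len(control_pool)
        )

    def test_profile_additive_over_disjoint_sets(self, control_pool, track):
        half = len(control_pool) // 2
        a = control_pool.subset(np.arange(half))
        b = control_pool.subset(np.arange(half, len(control_pool)))
        combined = fx.relative_end_profile(a, track) + fx.relative_end_profile(
            b, track
        )
        full = fx.relative_end_profile(control_pool, track)
        np.testing.assert_array_equal(combined.u_counts, full.u_counts)
        np.testing.assert_array_equal(combined.d_counts, full.d_counts)

    def test_u_mass_sits_left_of_d_mass(self, control_pool, track):
        profile = fx.relative_end_profile(control_pool, track)
        left = profile.positions < 0
        u_left = profile.frequencies("U")[left].sum()
        d_left = profile.frequencies("D")[left].sum()
        assert u_left > d_left

    def test_empty_track_rejected(self, control_pool):
        with pytest.raises(ValueError):
            fx.relative_end_profile(
                control_pool, fx.NucleosomeTrack(centers={}), 93
            )


class TestWithinCore:
    def test_all_ends_at_center(self, track):
        _, centers = track.single_chrom()
        c = int(centers[0])
        fs = fx.FragmentSet("s", "chrS", [c], [c + 1])
        profile = fx.relative_end_profile(fs, track)
        frac = fx.within_core_fraction(profile)
        assert frac["U"] == 1.0 and frac["D"] == 1.0

    def test_all_ends_outside_core(self, track):
        _, centers = track.single_chrom()
        c = int(centers[0])
        fs = fx.FragmentSet("s", "chrS", [c - 80], [c + 81])
        profile = fx.relative_end_profile(fs, track)
        frac = fx.within_core_fraction(profile)
        assert frac["U"] == 0.0 and frac["D"] == 0.0

    def test_short_exceeds_long_both_orientations(self, short_long, track):
        """Sub-147 bp fragments end inside the core more than >=170 bp ones."""
        short = fx.within_core_fraction(
            fx.relative_end_profile(short_long.short, track)
        )
        long = fx.within_core_fraction(
            fx.relative_end_profile(short_long.long, track)
        )
        assert short["U"] > long["U"]
        assert short["D"] > long["D"]


class TestPeakCalling:
    def test_single_spike_recovered(self):
        window = 93
        u = np.zeros(2 * window + 1, dtype=np.int64)
        u[-68 + window] = 1000
        profile = fx.EndProfile(window, u, np.zeros_like(u))
        peaks = fx.call_end_peaks(profile, "U")
        assert list(peaks.positions) == [-68]

    def test_flat_profile_has_no_peaks(self):
        window = 20
        flat = np.full(2 * window + 1, 7, dtype=np.int64)
        profile = fx.EndProfile(window, flat, np.zeros_like(flat))
        assert len(fx.call_end_peaks(profile, "U").positions) == 0

    def test_prominence_shift_invariant(self, short_profile):
        """Adding a uniform background must not move called peaks."""
        base = fx.call_end_peaks(short_profile, "U", min_prominence=0.004)
        shifted = fx.EndProfile(
            short_profile.window,
            short_profile.u_counts + 50,
            short_profile.d_counts,
        )
        # rescale the explicit prominence to the new normalisation
        scale = short_profile.u_counts.sum() / shifted.u_counts.sum()
        moved = fx.call_end_peaks(shifted, "U", min_prominence=0.004 * scale)
        np.testing.assert_array_equal(base.positions, moved.positions)

    def test_lattice_recovered_from_short_pool(self, short_profile):
        u = fx.call_end_peaks(short_profile, "U").within_core()
        assert -68 in u.positions
        gaps = np.diff(np.sort(u.positions))
        assert np.all(gaps == 10)


class TestPseudoFragments:
    def test_worked_example_143(self):
        u = EndPeakSet("U", np.array([-68]), np.array([1.0]))
        d = EndPeakSet("D", np.array([74]), np.array([1.0]))
        assert fx.pseudo_fragment_sizes(u, d) == [(-68, 74, 143)]

    def test_coincident_peaks_excluded(self):
        u = EndPeakSet("U", np.array([0]), np.array([1.0]))
        d = EndPeakSet("D", np.array([0]), np.array([1.0]))
        assert fx.pseudo_fragment_sizes(u, d) == []

    def test_inclusive_length_arithmetic(self):
        u = EndPeakSet("U", np.array([-59]), np.array([1.0]))
        d = EndPeakSet("D", np.array([63]), np.array([1.0]))
        assert fx.pseudo_fragment_sizes(u, d) == [(-59, 63, 123)]

    def test_all_ordered_pairs_present(self):
        u = EndPeakSet("U", np.array([-68, -8]), np.array([1.0, 1.0]))
        d = EndPeakSet("D", np.array([-20, 63]), np.array([1.0, 1.0]))
        out = fx.pseudo_fragment_sizes(u, d)
        assert all(d_ > u_ for u_, d_, _ in out)
        assert all(s == d_ - u_ + 1 for u_, d_, s in out)
        assert len(out) == 3  # (-8, -20) excluded

    def test_empty_peak_set_rejected(self):
        u = EndPeakSet("U", np.array([]), np.array([]))
        d = EndPeakSet("D", np.array([63]), np.array([1.0]))
        with pytest.raises(ValueError):
            fx.pseudo_fragment_sizes(u, d)


class TestSizeDistribution:
    def test_mode_of_small_set(self):
        fs = fx.FragmentSet("s", "chrS", [0, 0, 0], [166, 166, 150])
        _, _, mode = fx.size_distribution(fs)
        assert mode == 166

    def test_empty_set_has_no_mode(self):
        fs = fx.FragmentSet("s", "chrS", np.empty(0, int), np.empty(0, int))
        bins, counts, mode = fx.size_distribution(fs)
        assert mode is None
        assert counts.sum() == 0

    def test_histogram_counts_in_range_fragments(self, control_pool):
        bins, counts, _ = fx.size_distribution(control_pool, 50, 400)
        sizes = control_pool.sizes
        assert counts.sum() == int(((sizes >= 50) & (sizes <= 400)).sum())

    def test_mode_tie_breaks_to_smaller_size(self):
        fs = fx.FragmentSet("s", "chrS", [0, 0], [150, 166])
        _, _, mode = fx.size_distribution(fs)
        assert mode == 150
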