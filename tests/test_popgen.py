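"""Polarization, theta estimators, sweep statistics, windows and peaks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepfoot.errors import AlignmentError, ConfigError, EstimationError, InputError
from sweepfoot.popgen import (
    DerivedSFS, HaplotypeWindow, WindowStats,
    fay_wu_h_std, find_peaks, polarize, sliding_scan,
    stats_from_sfs, tajimas_d, theta_estimators, zengs_e,
)


def sfs(n, **classes):
    counts = [0] * (n - 1)
    for key, v in classes.items():
        counts[int(key[1:]) - 1] = v
    return DerivedSFS.from_counts(n, counts)


# ---------------------------------------------------------------------------
# polarize
# ---------------------------------------------------------------------------

class TestPolarize:
    def test_no_variation(self):
        w = HaplotypeWindow(("ACGT",) * 4, "ACGT")
        assert polarize(w).S == 0

    def test_singleton(self):
        w = HaplotypeWindow(("ACGT", "ACGT", "ACGT", "AGGT"), "ACGT")
        out = polarize(w)
        assert out.counts == (1, 0, 0)

    def test_triallelic_excluded(self):
        w = HaplotypeWindow(("A", "A", "C", "G"), "A")
        assert polarize(w).S == 0

    @pytest.mark.parametrize("bad", ["-", "N"])
    def test_gap_or_n_listwise_exclusion(self, bad):
        # variant column would be a singleton but carries a gap/N row
        w = HaplotypeWindow(("AC", "AC", f"{bad}C", "GC"), "AC")
        assert polarize(w).S == 0

    def test_unpolarizable_excluded(self):
        # two sample alleles, neither matching the ancestral base
        w = HaplotypeWindow(("C", "C", "G", "G"), "A")
        assert polarize(w).S == 0

    def test_fixed_derived_excluded(self):
        w = HaplotypeWindow(("C", "C", "C", "C"), "A")
        assert polarize(w).S == 0

    def test_high_frequency_site_counted(self):
        w = HaplotypeWindow(("C", "C", "C", "A"), "A")
        assert polarize(w).counts == (0, 0, 1)

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            HaplotypeWindow(("AC", "AC"), "ACG")

    def test_too_few_samples(self):
        with pytest.raises(InputError):
            HaplotypeWindow(("AC",), "AC")


# ---------------------------------------------------------------------------
# theta estimators
# ---------------------------------------------------------------------------

class TestThetaEstimators:
    def test_n2_singleton_all_equal_one(self):
        t = theta_estimators(sfs(2, S1=1))
        assert t.theta_pi == t.theta_w == t.theta_l == t.theta_h == 1.0

    def test_n4_singleton_hand_values(self):
        t = theta_estimators(sfs(4, S1=1))
        assert t.theta_pi == pytest.approx(0.5)
        assert t.theta_w == pytest.approx(6 / 11)
        assert t.theta_l == pytest.approx(1 / 3)
        assert t.theta_h == pytest.approx(1 / 6)

    def test_empty_sfs_all_zero(self):
        t = theta_estimators(DerivedSFS.from_counts(3, [0, 0]))
        assert t.theta_pi == t.theta_w == t.theta_l == t.theta_h == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(2, 10), st.data())
    def test_identity_pi_plus_h_is_2l(self, n, data):
        counts = data.draw(st.lists(st.integers(0, 5), min_size=n - 1,
                                    max_size=n - 1))
        t = theta_estimators(DerivedSFS.from_counts(n, counts))
        assert t.theta_pi + t.theta_h == pytest.approx(2 * t.theta_l, abs=1e-12)

    def test_pairwise_difference_oracle(self, rng):
        """theta_pi equals the mean pairwise Hamming distance computed
        directly from sequences built to carry a random SFS."""
        for _ in range(25):
            n = int(rng.integers(2, 7))
            L = 40
            anc = np.zeros(L, dtype=int)
            hap = np.zeros((n, L), dtype=int)
            for site in range(int(rng.integers(0, 10))):
                i = int(rng.integers(1, n))  # derived count
                carriers = rng.choice(n, size=i, replace=False)
                hap[carriers, site] = 1
            seqs = tuple("".join("AC"[x] for x in row) for row in hap)
            t = theta_estimators(polarize(HaplotypeWindow(seqs, "A" * L)))
            diffs = [np.sum(hap[i] != hap[j])
                     for i in range(n) for j in range(i + 1, n)]
            assert t.theta_pi == pytest.approx(np.mean(diffs))


# ---------------------------------------------------------------------------
# standardized statistics
# ---------------------------------------------------------------------------

def _tajimas_d_oracle(n, counts):
    """Independent transcription of the 1989 standardization."""
    S = sum(counts)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    pi = sum(2 * i * (n - i) * c / (n * (n - 1))
             for i, c in enumerate(counts, 1))
    return (pi - S / a1) / math.sqrt(c1 / a1 * S
                                     + c2 / (a1**2 + a2) * S * (S - 1))


class TestStatistics:
    def test_n2_all_statistics_zero(self):
        s = sfs(2, S1=1)
        assert tajimas_d(s) == 0
        assert fay_wu_h_std(s) == 0
        assert zengs_e(s) == 0

    def test_singleton_excess_gives_negative_d(self):
        assert tajimas_d(sfs(4, S1=1)) < 0

    def test_high_frequency_derived_lowers_h_raises_e(self):
        s = sfs(4, S3=1)
        assert fay_wu_h_std(s) < 0
        assert zengs_e(s) > 0

    def test_undefined_at_zero_segregating_sites(self):
        s = DerivedSFS.from_counts(4, [0, 0, 0])
        assert math.isnan(tajimas_d(s))
        assert math.isnan(fay_wu_h_std(s))
        assert math.isnan(zengs_e(s))

    def test_tajimas_d_matches_transcription_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            counts = rng.multinomial(int(rng.integers(1, 6)),
                                     np.ones(n - 1) / (n - 1))
            d = tajimas_d(DerivedSFS.from_counts(n, counts))
            ref = _tajimas_d_oracle(n, list(counts))
            if math.isfinite(ref):
                assert d == pytest.approx(ref, abs=1e-12)


# ---------------------------------------------------------------------------
# windows and peaks
# ---------------------------------------------------------------------------

def _const_locus(L, n=4):
    return HaplotypeWindow(("A" * L,) * n, "A" * L)


class TestSlidingScan:
    def test_single_window_when_window_equals_locus(self):
        track = sliding_scan(_const_locus(2000), 2000, 100)
        assert len(track) == 1
        assert (track[0].start, track[0].end) == (0, 2000)

    def test_window_arithmetic(self):
        track = sliding_scan(_const_locus(4000), 2000, 1000)
        assert [(w.start, w.end) for w in track] == [
            (0, 2000), (1000, 3000), (2000, 4000)]

    def test_whole_locus_window_equals_direct_statistics(self, rng):
        from sweepfoot.simulate import LocusConfig, gen_neutral_locus
        loc = gen_neutral_locus(LocusConfig(n=8, L=1000, seed=4))
        w = HaplotypeWindow(loc.sequences, loc.ancestral)
        track = sliding_scan(w, 1000, 1000)
        direct = stats_from_sfs(polarize(w), 0, 1000)
        assert track == [direct]

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            sliding_scan(_const_locus(100), 0, 10)
        with pytest.raises(ConfigError):
            sliding_scan(_const_locus(100), 200, 10)


class TestFindPeaks:
    def _w(self, start, D, H, E):
        return WindowStats(start, start + 100, D, H, E, S=3)

    def test_single_window_is_every_peak(self):
        w = self._w(0, 0.1, -0.2, 0.3)
        peaks = find_peaks([w])
        assert peaks == {"E_peak": w, "H_peak": w, "D_peak": w}

    def test_highest_e_selected(self):
        track = [self._w(0, 0, 0, 0.1), self._w(100, 0, 0, 2.0),
                 self._w(200, 0, 0, 0.3)]
        assert find_peaks(track)["E_peak"].start == 100

    def test_tie_broken_to_smallest_start(self):
        track = [self._w(0, 1.0, 0, 0), self._w(100, -1.0, 0, 0),
                 self._w(200, -1.0, 0, 0)]
        assert find_peaks(track)["D_peak"].start == 100
        track_e = [self._w(0, 0, 0, 2.0), self._w(100, 0, 0, 2.0)]
        assert find_peaks(track_e)["E_peak"].start == 0

    def test_undefined_windows_rejected(self):
        undef = WindowStats(0, 100, math.nan, math.nan, math.nan, S=0)
        with pytest.raises(EstimationError):
            find_peaks([undef])
        peaks = find_peaks([undef, self._w(100, 0.5, 0, 0)])
        assert peaks["D_peak"].start == 100
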