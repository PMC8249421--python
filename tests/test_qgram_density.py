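import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qgramfir import (
    FilterCoefficients,
    SequenceRecord,
    bin_signature,
    density_profile,
    enumerate_bins,
    fir_filter,
    uniform_window,
)
from tests.conftest import random_dna


class TestEnumerateBins:
    def test_monogram_alphabet(self):
        assert enumerate_bins(1).bins == ("A", "C", "G", "T")

    def test_twogram_alphabet(self):
        a = enumerate_bins(2)
        assert len(a) == 16
        assert a.bins[:5] == ("AA", "AC", "AG", "AT", "CA")
        assert a.bins[-1] == "TT"

    def test_trigram_extremes(self):
        a = enumerate_bins(3)
        assert len(a) == 64 and a.bins[0] == "AAA" and a.bins[-1] == "TTT"

    def test_lexicographic_order(self):
        a = enumerate_bins(2)
        assert list(a.bins) == sorted(a.bins)
        assert all(a.index(b) == i for i, b in enumerate(a.bins))

    @pytest.mark.parametrize("bad_q", [0, -1, 13])
    def test_out_of_range_q(self, bad_q):
        with pytest.raises(ValueError):
            enumerate_bins(bad_q)


class TestBinSignature:
    @pytest.mark.parametrize(
        "bin_word, expected",
        [
            ("A", [1, 1, 0, 0, 0, 0]),
            ("T", [0, 0, 0, 1, 0, 0]),
            ("G", [0, 0, 0, 0, 0, 1]),
            ("C", [0, 0, 1, 0, 1, 0]),  # literal positional scan: C at positions 3 and 5
            ("AA", [1, 0, 0, 0, 0]),
            ("AC", [0, 1, 0, 0, 0]),
            ("AG", [0, 0, 0, 0, 0]),
            ("TT", [0, 0, 0, 0, 0]),
        ],
    )
    def test_worked_example_signatures(self, bin_word, expected):
        sig = bin_signature("AACTCG", bin_word)
        assert sig.values.tolist() == expected
        assert len(sig) == 6 - len(bin_word) + 1

    def test_positions_overlapping_n_are_zero(self):
        assert bin_signature("ANA", "A").values.tolist() == [1, 0, 1]
        assert bin_signature("ANAA", "AA").values.tolist() == [0, 0, 1]

    def test_bin_longer_than_sequence(self):
        with pytest.raises(ValueError, match="exceeds"):
            bin_signature("ACG", "ACGT")

    def test_completeness_partition(self, rng):
        """For an N-free sequence, every position matches exactly one bin."""
        for q in (1, 2, 3):
            seq = random_dna(rng, 50)
            total = sum(bin_signature(seq, b).values for b in enumerate_bins(q).bins)
            assert np.array_equal(total, np.ones(50 - q + 1))


class TestFirFilter:
    def test_worked_example_responses(self, example_coeffs):
        ya = fir_filter([1, 1, 0, 0, 0, 0], example_coeffs)
        yt = fir_filter([0, 0, 0, 1, 0, 0], example_coeffs)
        np.testing.assert_allclose(ya, [0.2, 0.3, 0.4, 0.7, 0.4, 0.0], atol=1e-15)
        np.testing.assert_allclose(yt, [0.0, 0.0, 0.0, 0.2, 0.1, 0.3], atol=1e-15)

    def test_impulse_response_is_taps(self, rng):
        taps = rng.normal(size=4)
        y = fir_filter([1, 0, 0, 0, 0], FilterCoefficients(taps))
        np.testing.assert_allclose(y, np.append(taps, 0.0))

    def test_zero_input_zero_output(self, example_coeffs):
        assert not fir_filter(np.zeros(8), example_coeffs).any()

    def test_output_truncated_to_input_length(self, example_coeffs):
        assert len(fir_filter(np.ones(6), example_coeffs)) == 6

    @pytest.mark.parametrize("bad", [[], [1.0, np.nan], [np.inf]])
    def test_invalid_input_rejected(self, bad, example_coeffs):
        with pytest.raises(ValueError):
            fir_filter(np.array(bad), example_coeffs)

    @settings(deadline=None, derandomize=True)
    @given(
        x=st.lists(st.floats(-100, 100), min_size=1, max_size=40),
        z=st.lists(st.floats(-100, 100), min_size=1, max_size=40),
        a=st.floats(-10, 10),
    )
    def test_linearity(self, x, z, a):
        n = min(len(x), len(z))
        x, z = np.array(x[:n]), np.array(z[:n])
        b = FilterCoefficients(np.array([0.5, -1.0, 2.0]))
        lhs = fir_filter(a * x + z, b)
        rhs = a * fir_filter(x, b) + fir_filter(z, b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_shift_property(self, example_coeffs):
        """Delaying the impulse shifts the truncated response by one position."""
        y0 = fir_filter([1, 0, 0, 0, 0, 0], example_coeffs)
        y1 = fir_filter([0, 1, 0, 0, 0, 0], example_coeffs)
        np.testing.assert_allclose(y1[1:], y0[:-1])
        assert y1[0] == 0.0


class TestUniformWindow:
    def test_unit_taps(self):
        np.testing.assert_array_equal(uniform_window(4).b, np.ones(4))

    def test_normalized_taps(self):
        np.testing.assert_allclose(uniform_window(4, normalize=True).b, np.full(4, 0.25))

    def test_degenerate_width_one(self):
        assert uniform_window(1).b.tolist() == [1.0]

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            uniform_window(0)


def brute_force_trailing_count(seq: str, bin_word: str, W: int) -> np.ndarray:
    """Independent oracle: occurrences of bin_word starting in the trailing
    W signature positions ending at each position (inclusive)."""
    q = len(bin_word)
    n_pos = len(seq) - q + 1
    out = np.zeros(n_pos)
    for i in range(n_pos):
        lo = max(0, i - W + 1)
        out[i] = sum(seq[a : a + q] == bin_word for a in range(lo, i + 1))
    return out


class TestDensityProfile:
    def test_worked_example_profile(self, example_record, example_coeffs):
        prof = density_profile(example_record, 1, example_coeffs)
        assert prof.rows.shape == (4, 6)
        np.testing.assert_allclose(prof.rows[0], [0.2, 0.3, 0.4, 0.7, 0.4, 0.0], atol=1e-15)

    def test_homopolymer_unit_window(self):
        prof = density_profile(SequenceRecord("s", "AAAA"), 1, uniform_window(1))
        np.testing.assert_array_equal(prof.rows[0], np.ones(4))
        assert not prof.rows[1:].any()

    def test_unit_window_counts_match_brute_force(self, rng):
        """Unit-window FIR densities are trailing-window occurrence counts."""
        for _ in range(25):
            n = int(rng.integers(10, 200))
            seq = random_dna(rng, n)
            q = int(rng.choice([1, 2, 3]))
            W = int(rng.choice([1, 4, 9]))
            prof = density_profile(SequenceRecord("s", seq), q, uniform_window(W))
            for j, b in enumerate(enumerate_bins(q).bins):
                np.testing.assert_array_equal(
                    prof.rows[j], brute_force_trailing_count(seq, b, W)
                )

    def test_unit_window_entries_bounded_integers(self, rng):
        seq = random_dna(rng, 120)
        prof = density_profile(SequenceRecord("s", seq), 2, uniform_window(9))
        assert np.array_equal(prof.rows, np.round(prof.rows))
        assert prof.rows.min() >= 0 and prof.rows.max() <= 9

    def test_sequence_shorter_than_q(self, example_coeffs):
        with pytest.raises(ValueError, match="shorter"):
            density_profile(SequenceRecord("s", "AC"), 3, example_coeffs)

    def test_n_contributes_to_no_bin(self):
        prof = density_profile(SequenceRecord("s", "ANGT"), 1, uniform_window(1))
        assert prof.rows[:, 1].sum() == 0.0
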