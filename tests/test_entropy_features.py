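import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpfdna.entropy_features import (
    cpf_vector,
    embed_lf,
    lf_entropy,
    local_frequencies,
    partial_sum_entropy,
)
from cpfdna.sequence_io import DnaRecord

from _oracles import brute_lf_entropy, brute_partial_sum_entropy

nonneg = st.lists(
    st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=20
)


class TestPartialSumEntropy:
    @pytest.mark.parametrize(
        "x, expected",
        [
            # published worked examples for length-8 indicator rows
            ((1, 0, 0, 0, 0, 0, 0, 0), 3.0),
            ((0, 0, 0, 0, 0, 0, 0, 1), 0.0),
            ((1, 0, 0, 0, 0, 0, 1, 0), 2.9219),
            ((1, 0, 0, 0, 0, 0, 0, 1), 2.9477),
            ((1, 1, 0, 0, 0, 0, 0, 0), 2.9736),
        ],
    )
    def test_published_values(self, x, expected):
        assert partial_sum_entropy(x) == pytest.approx(expected, abs=1e-3)

    def test_scale_invariance_example(self):
        assert partial_sum_entropy((2, 0, 0, 0, 0, 0, 0, 0)) == pytest.approx(3.0)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            partial_sum_entropy([1.0, -0.5])

    def test_all_zero_returns_zero(self):
        assert partial_sum_entropy([0.0, 0.0, 0.0]) == 0.0

    @settings(derandomize=True)
    @given(x=nonneg, c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, x, c):
        h = partial_sum_entropy(x)
        h_scaled = partial_sum_entropy([c * v for v in x])
        assert h_scaled == pytest.approx(h, abs=1e-9)

    @settings(derandomize=True)
    @given(x=nonneg)
    def test_range_bound(self, x):
        h = partial_sum_entropy(x)
        assert 0.0 <= h <= math.log2(len(x)) + 1e-12

    def test_maximum_attained_only_by_front_loaded_mass(self):
        n = 8
        assert partial_sum_entropy([5.0] + [0.0] * (n - 1)) == pytest.approx(
            math.log2(n)
        )
        # any mass beyond position 1 strictly lowers the entropy
        assert partial_sum_entropy([1, 0.1, 0, 0, 0, 0, 0, 0]) < math.log2(n)


class TestLocalFrequencies:
    @pytest.mark.parametrize(
        "positions, expected",
        [
            ([1, 8], [1.0, 1.0 / 7.0]),
            ([1], [1.0]),
            ([2, 4, 5], [0.5, 0.5, 1.0]),
            ([], []),
        ],
    )
    def test_reciprocal_gaps(self, positions, expected):
        assert local_frequencies(positions) == pytest.approx(expected)

    def test_non_increasing_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            local_frequencies([3, 3])
        with pytest.raises(ValueError, match="strictly increasing"):
            local_frequencies([0, 2])


class TestEmbedLf:
    def test_placement(self):
        np.testing.assert_allclose(
            embed_lf([1, 6], 8), [1, 0, 0, 0, 0, 0.2, 0, 0]
        )

    def test_empty_positions(self):
        np.testing.assert_array_equal(embed_lf([], 5), np.zeros(5))

    def test_adjacent_occurrences(self):
        np.testing.assert_allclose(
            embed_lf([1, 2], 8), [1, 1, 0, 0, 0, 0, 0, 0]
        )

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            embed_lf([9], 8)


class TestLfEntropy:
    @pytest.mark.parametrize(
        "positions, expected",
        [
            ([1, 7], 2.9966),
            ([1, 6], 2.9942),
            ([1, 5], 2.9911),
            ([1, 4], 2.9868),
            ([1, 3], 2.9808),
            ([1, 2], 2.9736),
        ],
    )
    def test_published_two_occurrence_values(self, positions, expected):
        assert lf_entropy(positions, 8) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("r, m", [(1, 8), (3, 8), (8, 8), (2, 5)])
    def test_single_occurrence_closed_form(self, r, m):
        assert lf_entropy([r], m) == pytest.approx(math.log2(m - r + 1))

    def test_absent_word_scores_zero(self):
        assert lf_entropy([], 10) == 0.0

    def test_consistent_trend_of_second_occurrence(self):
        """Moving the second of two occurrences earlier strictly lowers h."""
        values = [lf_entropy([1, j], 8) for j in range(8, 1, -1)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_front_weighting_of_single_occurrence(self):
        """Shifting a lone occurrence later never increases the entropy."""
        values = [lf_entropy([r], 8) for r in range(1, 9)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestOracleEquivalence:
    def test_all_length_8_indicators_match_brute_force(self):
        """Both entropy operators agree with an independent brute-force
        evaluation on all 256 binary indicator rows of length 8."""
        for bits in itertools.product((0, 1), repeat=8):
            assert partial_sum_entropy(bits) == pytest.approx(
                brute_partial_sum_entropy(bits), abs=1e-12
            )
            positions = [i + 1 for i, b in enumerate(bits) if b]
            assert lf_entropy(positions, 8) == pytest.approx(
                brute_lf_entropy(bits), abs=1e-12
            )


class TestCpfVector:
    def test_acgt_components(self):
        vec = cpf_vector(DnaRecord("s1", "ACGT"))
        by_word = dict(zip(vec.labels, vec.values))
        assert by_word["RY"] == pytest.approx(1.5567, abs=1e-3)
        assert by_word["MM"] == pytest.approx(math.log2(3))
        for absent in ("RR", "YY", "KM", "WW"):
            assert by_word[absent] == 0.0

    def test_single_letter_mapped_sequences(self):
        vec = cpf_vector(DnaRecord("s1", "AAAA"))
        by_word = dict(zip(vec.labels, vec.values))
        # A maps to the first letter of every scheme; all words containing
        # a second letter are absent
        for word in vec.labels:
            if word not in ("RR", "MM", "WW"):
                assert by_word[word] == 0.0
        assert by_word["RR"] == pytest.approx(
            lf_entropy([1, 2, 3], 3)
        )

    @settings(derandomize=True, max_examples=30)
    @given(residues=st.text(alphabet="ACGT", min_size=2, max_size=50))
    def test_always_12_components_within_bounds(self, residues):
        vec = cpf_vector(DnaRecord("s", residues))
        m = len(residues) - 1
        assert len(vec) == 12
        assert np.all(vec.values >= 0)
        assert np.all(vec.values <= math.log2(m) + 1e-12) if m > 1 else True

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            cpf_vector(DnaRecord("s1", "A"))

    def test_general_window_size_dimension(self):
        vec = cpf_vector(DnaRecord("s1", "ACGTACGT"), k=3)
        assert len(vec) == 3 * 2 ** 3
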