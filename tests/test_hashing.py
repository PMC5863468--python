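"""Naive oracle, incremental engine equivalence, and encoding accounting."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fshash import (
    UNENCODABLE,
    count_encodings,
    decode_hash,
    encode_symbol,
    fsh_hash_all,
    hash_to_bits,
    naive_hash_all,
    naive_hash_at,
    parse_seed,
    table_for,
)

from conftest import random_dna, random_pattern

X = "ACTGACTGGA"  # worked-example sequence


class TestEncode:
    @pytest.mark.parametrize(
        "c, code", [("A", 0b00), ("C", 0b01), ("G", 0b10), ("T", 0b11), ("t", 0b11)]
    )
    def test_codes(self, c, code):
        assert encode_symbol(c) == code

    @pytest.mark.parametrize("c", ["N", "n", "X", "-", " ", "U"])
    def test_unencodable_sentinel(self, c):
        assert encode_symbol(c) == UNENCODABLE


class TestNaiveHash:
    def test_worked_example_bit_strings(self, example_seed):
        expected = ["101100101100", "101001001001", "001011010011"]
        got = [hash_to_bits(naive_hash_at(X, i, example_seed), example_seed)
               for i in range(3)]
        assert got == expected

    def test_worked_example_decimals(self, example_seed):
        vec = naive_hash_all(X, example_seed)
        assert list(vec.hashes) == [2860, 2633, 723]
        assert list(vec.positions) == [0, 1, 2]

    def test_single_symbol(self):
        assert naive_hash_at("A", 0, parse_seed("1")) == 0

    def test_position_out_of_range(self, example_seed):
        with pytest.raises(ValueError):
            naive_hash_at(X, 3, example_seed)

    def test_unencodable_symbol_raises(self, example_seed):
        # N sits at matched position 2; an N at a don't-care is harmless
        with pytest.raises(ValueError, match="unencodable"):
            naive_hash_at("ACNGACTG", 0, example_seed)
        assert naive_hash_at("ANTGACTG", 0, example_seed) == naive_hash_at(
            "AATGACTG", 0, example_seed
        )

    def test_short_sequence_empty_vector(self, example_seed):
        assert len(naive_hash_all("ACTGACT", example_seed)) == 0

    def test_all_positions_match_pointwise(self, rng, example_seed):
        x = random_dna(rng, 200)
        vec = naive_hash_all(x, example_seed)
        for pos, h in zip(vec.positions, vec.hashes):
            assert int(h) == naive_hash_at(x, int(pos), example_seed)

    def test_decode_round_trip(self, rng, example_seed):
        x = random_dna(rng, 60)
        vec = naive_hash_all(x, example_seed)
        for pos, h in zip(vec.positions, vec.hashes):
            qgram = "".join(x[int(pos) + k] for k in example_seed.shape)
            assert decode_hash(int(h), example_seed) == qgram


class TestFshEngine:
    def test_reuse_step_bit_level(self, example_seed):
        # hash(1) from hash(0): shift 2, mask offsets {2,3,4,5,8,9}, insert 3
        table = table_for(example_seed)
        plan = table.plans[1]
        reused = (2860 >> plan.bit_shift) & plan.keep_mask
        assert reused == 520
        v = reused
        for k, c in [(0, "C"), (4, "C"), (7, "G")]:
            v |= encode_symbol(c) << (2 * example_seed.m[k])
        assert v == 2633

    def test_matches_oracle_on_worked_example(self, example_seed):
        assert fsh_hash_all(X, example_seed) == naive_hash_all(X, example_seed)

    def test_mismatched_table_rejected(self, example_seed):
        other = table_for(parse_seed("1111"))
        with pytest.raises(ValueError):
            fsh_hash_all(X, example_seed, other)

    def test_segments_split_on_ambiguity(self, example_seed):
        x = "ACTGACTGGA" + "N" * 3 + "ACTGACTGGA"
        vec = fsh_hash_all(x, example_seed)
        assert list(vec.hashes) == [2860, 2633, 723] * 2
        assert list(vec.positions) == [0, 1, 2, 13, 14, 15]

    def test_segment_count_accounting(self, rng, example_seed):
        x = random_dna(rng, 400, n_prob=0.05)
        import re

        segs = re.findall("[ACGT]+", x)
        expected = sum(max(0, len(s) - example_seed.span + 1) for s in segs)
        assert len(fsh_hash_all(x, example_seed)) == expected

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_oracle_equivalence_random(self, ns):
        r = np.random.default_rng(ns)
        seed = parse_seed(random_pattern(r))
        x = random_dna(r, int(r.integers(0, 500)), n_prob=0.02)
        assert fsh_hash_all(x, seed) == naive_hash_all(x, seed)

    def test_all_ones_seed_single_insertion_steady_state(self):
        seed = parse_seed("1" * 8)
        table = table_for(seed)
        assert len(table.plans[1].missing) == 1


class TestCountEncodings:
    def test_naive_per_symbol_is_weight(self, rng, example_seed):
        x = random_dna(rng, 5000)
        total, per_symbol = count_encodings(x, example_seed, "naive")
        assert total == 6 * (5000 - 7)
        assert per_symbol == 6

    def test_fsh_per_symbol_worked_seed(self, rng, example_seed):
        x = random_dna(rng, 5000)
        _, per_symbol = count_encodings(x, example_seed, "fsh")
        assert per_symbol == 3

    @pytest.mark.parametrize("pattern", ["10101010101", "1" * 22, "1" * 5])
    def test_fsh_per_symbol_one_for_rolling_seeds(self, rng, pattern):
        x = random_dna(rng, 3000)
        _, per_symbol = count_encodings(x, parse_seed(pattern), "fsh")
        assert per_symbol == 1

    def test_steady_state_equals_weight_minus_best_kept(self, rng):
        for ns in range(10):
            r = np.random.default_rng(ns)
            seed = parse_seed(random_pattern(r))
            if seed.span == 1:
                continue
            x = random_dna(r, 2000)
            _, per_symbol = count_encodings(x, seed, "fsh")
            from fshash import best_previous

            _, kept = best_previous(table_for(seed), seed.span - 1)
            assert per_symbol == seed.weight - kept

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fsh_never_exceeds_naive(self, ns):
        r = np.random.default_rng(ns)
        seed = parse_seed(random_pattern(r))
        x = random_dna(r, int(r.integers(0, 300)), n_prob=0.03)
        naive_total, _ = count_encodings(x, seed, "naive")
        fsh_total, _ = count_encodings(x, seed, "fsh")
        assert fsh_total <= naive_total

    def test_empty_sequence(self, example_seed):
        assert count_encodings("", example_seed, "fsh") == (0, Fraction(0))

    def test_bad_mode(self, example_seed):
        with pytest.raises(ValueError):
            count_encodings("ACGT", example_seed, "quick")
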