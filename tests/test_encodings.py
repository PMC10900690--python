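import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiflex import (InteractionEncoding, InvalidGenotypeError, cartesian_encoding,
                     encode_pair, get_encoding, mlg_counts, mlg_filter,
                     read_encoding_table, xor_encoding)
from epiflex.errors import EmptyInputError

GT = [0, 1, 2]


@pytest.mark.parametrize("g1, g2, expected", [
    (1, 0, 1), (1, 1, 0), (2, 1, 1), (2, 2, 0), (0, 0, 0), (0, 2, 0),
])
def test_xor_is_parity_of_heterozygosity(g1, g2, expected):
    assert xor_encoding().table[(g1, g2)] == expected
    # the literal double-mod formula
    assert xor_encoding().table[(g1, g2)] == ((g1 % 2) + (g2 % 2)) % 2


def test_xor_symmetric_and_binary():
    table = xor_encoding().table
    for a, b in itertools.product(GT, repeat=2):
        assert table[(a, b)] == table[(b, a)]
        assert table[(a, b)] in (0.0, 1.0)
        assert table[(a, a)] == 0.0


def test_cartesian_is_product():
    table = cartesian_encoding().table
    for a, b in itertools.product(GT, repeat=2):
        assert table[(a, b)] == a * b
    assert table[(2, 2)] == 4
    assert all(table[(0, x)] == 0 for x in GT)


def test_constant_zero_custom_encoding():
    enc = InteractionEncoding("null", {t: 0.0 for t in itertools.product(GT, repeat=2)})
    out = encode_pair([0, 1, 2, 2], [2, 1, 0, 2], enc)
    assert np.array_equal(out, np.zeros(4))


def test_encoding_table_must_be_total():
    table = {t: 1.0 for t in itertools.product(GT, repeat=2)}
    table.pop((2, 2))
    with pytest.raises(ValueError, match="not total"):
        InteractionEncoding("partial", table)


def test_encode_pair_propagates_missing_and_rejects_bad_codes():
    out = encode_pair([1.0, np.nan, 2.0], [1.0, 1.0, np.nan], "cartesian")
    assert out[0] == 1.0 and np.isnan(out[1]) and np.isnan(out[2])
    with pytest.raises(InvalidGenotypeError, match="sample index 1"):
        encode_pair([0.0, 3.0], [1.0, 1.0], "xor")


def test_penetrance_table_roundtrip(tmp_path):
    path = tmp_path / "enc.tsv"
    rows = ["g1\tg2\tvalue"]
    rows += [f"{a}\t{b}\t{(a % 2 + b % 2) % 2}" for a, b in itertools.product(GT, repeat=2)]
    path.write_text("\n".join(rows) + "\n")
    enc = read_encoding_table(path, name="xor_from_file")
    assert enc.table == get_encoding("xor").table


def test_mlg_counts_diagonal_and_total():
    counts = mlg_counts([0, 1, 2], [0, 1, 2])
    assert len(counts.counts) == 9
    assert counts.counts[(0, 0)] == counts.counts[(1, 1)] == counts.counts[(2, 2)] == 1
    assert counts.total == 3
    assert sum(v for k, v in counts.counts.items() if k not in [(0, 0), (1, 1), (2, 2)]) == 0


def test_mlg_counts_conserved_under_hwe_draws(rng):
    g1 = rng.binomial(2, 0.5, 100).astype(float)
    g2 = rng.binomial(2, 0.5, 100).astype(float)
    assert mlg_counts(g1, g2).total == 100
    perm = rng.permutation(100)
    assert mlg_counts(g1[perm], g2[perm]).counts == mlg_counts(g1, g2).counts


def test_mlg_counts_empty_input_errors():
    with pytest.raises(EmptyInputError):
        mlg_counts([], [])


@given(st.integers(0, 20), st.integers(0, 20))
@settings(deadline=None)
def test_mlg_filter_thresholds(base, min_count):
    counts = mlg_counts(
        np.repeat(GT, 3 * max(base, 1)), np.tile(GT, 3 * max(base, 1)))
    # every MLG appears max(base,1) times in this balanced layout
    assert mlg_filter(counts, min_count) == (counts.min_count() >= min_count)
    assert mlg_filter(counts, 0) is True


def test_mlg_filter_paper_style_thresholds():
    even = {t: 10 for t in itertools.product(GT, repeat=2)}
    from epiflex import MLGCount
    assert mlg_filter(MLGCount(even), 10) is True
    uneven = dict(even)
    uneven[(2, 2)] = 4
    assert mlg_filter(MLGCount(uneven), 5) is False
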