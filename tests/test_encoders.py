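"""Unit and property tests for the six sequence encodings.

The MMI encoder is checked against a deliberately separate brute-force
implementation written as plain loops over windows and tuple sets.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourmc import encoders
from fourmc.encoders import (
    T2,
    T3,
    encode_binary,
    encode_dataset,
    encode_kmer_onehot,
    encode_mmi,
    encode_ncp,
    encode_ncpnf,
    encode_sequence,
    scheme_shape,
)
from fourmc.synthetic import SyntheticSpec, generate

seq41 = st.text(alphabet="ACGTN", min_size=41, max_size=41)


# ---------------------------------------------------------------- binary ----
class TestBinary:
    def test_printed_symbol_vectors(self):
        m = encode_binary("ACGTN").values
        assert np.array_equal(m, np.vstack([np.eye(5)[:4], np.zeros(5)]))

    @settings(max_examples=50, derandomize=True)
    @given(seq41)
    def test_one_hot_row_sums(self, seq):
        m = encode_binary(seq).values
        assert m.shape == (41, 5)
        expected = np.array([0.0 if s == "N" else 1.0 for s in seq])
        assert np.array_equal(m.sum(axis=1), expected)

    def test_invalid_symbol(self):
        with pytest.raises(ValueError, match="invalid symbols"):
            encode_binary("ACGTX")


# ----------------------------------------------------------------- k-mer ----
class TestKmerOnehot:
    @pytest.mark.parametrize("k,rows,channels", [(2, 40, 25), (3, 39, 125)])
    def test_window_counts_for_41nt(self, k, rows, channels):
        seq = "ACGT" * 10 + "A"
        m = encode_kmer_onehot(seq, k).values
        assert m.shape == (rows, channels)
        assert np.array_equal(m.sum(axis=1), np.ones(rows))

    def test_definition_case(self):
        m = encode_kmer_onehot("AAA", 2).values
        idx_aa = encoders._KMER_INDEX[2]["AA"]
        assert m.shape == (2, 25)
        assert np.array_equal(np.nonzero(m)[1], [idx_aa, idx_aa])

    def test_channel_order_frozen(self):
        # lexicographic over A,C,G,N,T: AA=0, AC=1, ..., TT=24
        assert encoders._KMER_INDEX[2]["AA"] == 0
        assert encoders._KMER_INDEX[2]["AC"] == 1
        assert encoders._KMER_INDEX[2]["TT"] == 24
        assert encoders._KMER_INDEX[3]["TTT"] == 124

    @pytest.mark.parametrize("k", [1, 4])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            encode_kmer_onehot("ACGT" * 11, k)


# ------------------------------------------------------------------- NCP ----
class TestNCP:
    def test_printed_coordinate_table(self):
        m = encode_ncp("ACGTN").values
        assert np.array_equal(
            m, [[1, 1, 1], [0, 0, 1], [1, 0, 0], [0, 1, 0], [0, 0, 0]])

    @settings(max_examples=50, derandomize=True)
    @given(seq41)
    def test_x_channel_marks_purines(self, seq):
        m = encode_ncp(seq).values
        assert np.array_equal(
            m[:, 0], [1.0 if s in "AG" else 0.0 for s in seq])

    def test_column_sums_of_alternating_composition(self):
        # "ACGT"x10 + "A": 11 A, 10 each C/G/T -> 21 purines, 21 weak-bond,
        # 21 amino (brute-force count)
        m = encode_ncp("ACGT" * 10 + "A").values
        assert m.shape == (41, 3)
        assert np.array_equal(m.sum(axis=0), [21, 21, 21])


# ----------------------------------------------------------------- NCPNF ----
class TestNCPNF:
    def test_constant_sequence_density_one(self):
        m = encode_ncpnf("A" * 41).values
        assert np.array_equal(m, np.ones((41, 4)))

    def test_cumulative_density_small_case(self):
        m = encode_ncpnf("AC" + "A" * 39).values
        assert np.array_equal(m[0], [1, 1, 1, 1.0])
        assert np.array_equal(m[1], [0, 0, 1, 0.5])
        # third base is the 2nd A among 3 positions
        assert m[2, 3] == pytest.approx(2 / 3)

    @settings(max_examples=50, derandomize=True)
    @given(seq41)
    def test_density_in_unit_interval_and_first_is_one(self, seq):
        d = encode_ncpnf(seq).values[:, 3]
        assert d[0] == 1.0
        assert np.all((d > 0) & (d <= 1))

    def test_pad_to_five_adds_zero_channel(self):
        m = encode_ncpnf("A" * 41, pad_to_five=True).values
        assert m.shape == (41, 5)
        assert np.array_equal(m[:, 4], np.zeros(41))


# ------------------------------------------------------------------- MMI ----
def mmi_bruteforce(seq: str) -> np.ndarray:
    """Independent reference: explicit loops over windows and tuple sets."""
    L = len(seq)
    order = "ACGTN"

    def canon(t):
        return "".join(sorted(t, key=order.index))

    def f1(a):
        return sum(1 for s in seq if s == a) / L

    def f2(pair):
        hits = sum(1 for i in range(L - 1) if canon(seq[i:i + 2]) == canon(pair))
        return hits / (L - 1)

    def f3(trip):
        hits = sum(1 for i in range(L - 2) if canon(seq[i:i + 3]) == canon(trip))
        return hits / (L - 2)

    def i2(a, b):
        v, fa, fb = f2(a + b), f1(a), f1(b)
        if v == 0 or fa == 0 or fb == 0:
            return 0.0
        return v * math.log(v / (fa * fb))

    out = [f1(a) for a in order]
    for pair in itertools.combinations_with_replacement(order, 2):
        out.append(i2(*pair))
    for a, b, c in itertools.combinations_with_replacement(order, 3):
        v = f3(a + b + c)
        num, den = v * f1(c), f2(a + c) * f2(b + c)
        sub = 0.0 if (v == 0 or num == 0 or den == 0) else v * math.log(num / den)
        out.append(i2(a, b) - sub)
    return np.array(out)


class TestMMI:
    def test_tuple_sets(self):
        assert len(T2) == 15 and len(T3) == 35
        assert T2[:5] == ("AA", "AC", "AG", "AT", "AN")
        # complete multiset includes the members missing from smaller listings
        assert "GNN" in T3 and "TNN" in T3

    def test_feature_count_is_55(self):
        assert encode_mmi("ACGT" * 10 + "C").values.shape == (55, 1)

    def test_constant_sequence(self):
        v = encode_mmi("A" * 41).values.ravel()
        assert v[0] == 1.0                 # f(A)
        assert np.array_equal(v[1:5], np.zeros(4))
        # I2(A,A) = 1 * ln(1/(1*1)) = 0; all other terms hit the zero rule
        assert np.allclose(v[5:], 0.0)

    def test_agrees_with_bruteforce_on_random_sequences(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGTN"), size=41,
                                     p=[0.23, 0.27, 0.23, 0.23, 0.04]))
            got = encode_mmi(seq).values.ravel()
            assert np.allclose(got, mmi_bruteforce(seq), atol=1e-12)


# ------------------------------------------------------------ composition ---
class TestEncodeDataset:
    @pytest.mark.parametrize("scheme,shape", [
        ("BE", (41, 5)), ("DNC", (40, 25)), ("TNC", (39, 125)),
        ("NCP", (41, 3)), ("NCPNF", (41, 4)), ("MMI", (55, 1)),
    ])
    def test_stacked_shapes(self, tiny_ds, scheme, shape):
        X, y = encode_dataset(tiny_ds, scheme)
        assert X.shape == (len(tiny_ds),) + shape
        assert scheme_shape(scheme) == shape
        assert np.array_equal(y, tiny_ds.labels())

    def test_empty_dataset_rejected(self):
        from fourmc.seqio import LabeledDataset

        with pytest.raises(ValueError, match="empty"):
            encode_dataset(LabeledDataset([]), "BE")

    def test_mixed_lengths_rejected(self):
        from fourmc.seqio import LabeledDataset, SequenceRecord

        ds = LabeledDataset([SequenceRecord("a", "ACGTC", 1),
                             SequenceRecord("b", "ACGTCA", 0)])
        with pytest.raises(ValueError, match="mixed"):
            encode_dataset(ds, "BE")

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            encode_sequence("ACGT", "EIIP")


@settings(max_examples=30, derandomize=True)
@given(seq41, st.sampled_from(encoders.SCHEMES))
def test_encoders_are_pure_and_finite(seq, scheme):
    a = encode_sequence(seq, scheme).values
    b = encode_sequence(seq, scheme).values
    assert np.array_equal(a, b)
    assert np.all(np.isfinite(a))
    assert a.shape == scheme_shape(scheme)


def test_synthetic_records_encode_under_every_scheme():
    ds = generate(SyntheticSpec(n_per_class=5, seed=0))
    for scheme in encoders.SCHEMES:
        X, _ = encode_dataset(ds, scheme)
        assert X.shape[1:] == scheme_shape(scheme)
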