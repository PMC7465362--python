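"""Six nucleotide feature encodings for fixed-length DNA windows.

Every encoder is a pure function from a sequence string over {A,C,G,T,N} to a
(positions, channels) float matrix suitable for a 1-D convolutional model:

====== =================== =========================================
scheme shape for L = 41    description
====== =================== =========================================
BE     (41, 5)             per-base one-hot, channel order A,C,G,T,N
DNC    (40, 25)            overlapping 2-mer one-hot
TNC    (39, 125)           overlapping 3-mer one-hot
NCP    (41, 3)             chemical-property bits (ring, H-bond, group)
NCPNF  (41, 4)             NCP plus cumulative nucleotide density
MMI    (55, 1)             multivariate mutual-information feature vector
====== =================== =========================================

BE/NCP use the conventional symbol order A,C,G,T,N. The k-mer channel order is
lexicographic over the alphabetical symbol order A,C,G,N,T and is frozen: the
channel index of a k-mer never changes between versions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .seqio import LabeledDataset

#: symbol order for BE one-hot channels and NCP rows (N encodes to all-zeros)
BE_ORDER = "ACGTN"

#: alphabetical symbol order used for the k-mer channel alphabet
KMER_ORDER = "ACGNT"

#: chemical-property coordinates (ring structure, hydrogen bond, functional
#: group): purines A/G carry two rings (x=1), A/T pair through weak hydrogen
#: bonds (y=1), amino bases A/C get z=1; N is unknown and maps to the origin.
CHEMICAL_PROPERTY_TABLE: dict[str, tuple[int, int, int]] = {
    "A": (1, 1, 1),
    "C": (0, 0, 1),
    "G": (1, 0, 0),
    "T": (0, 1, 0),
    "N": (0, 0, 0),
}

SCHEMES = ("BE", "DNC", "TNC", "NCP", "NCPNF", "MMI")

#: schemes whose rows index sequence positions (and hence admit a gradient
#: path from the model input back to individual bases); MMI is a global
#: composition vector and does not
POSITIONAL_SCHEMES = ("BE", "DNC", "TNC", "NCP", "NCPNF")


@dataclass(frozen=True)
class EncodedMatrix:
    """A (positions, channels) encoding of one sequence window."""

    values: np.ndarray
    scheme: str
    source_id: str = ""

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError("EncodedMatrix values must be 2-D (positions, channels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EncodedMatrix values must be finite")


def scheme_shape(scheme: str, length: int = 41, ncpnf_pad_to_five: bool = False) -> tuple[int, int]:
    """(positions, channels) produced by ``scheme`` on a window of ``length``."""
    scheme = scheme.upper()
    if scheme == "BE":
        return (length, 5)
    if scheme == "DNC":
        return (length - 1, 25)
    if scheme == "TNC":
        return (length - 2, 125)
    if scheme == "NCP":
        return (length, 3)
    if scheme == "NCPNF":
        return (length, 5 if ncpnf_pad_to_five else 4)
    if scheme == "MMI":
        return (55, 1)
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid symbols {sorted(bad)}; alphabet is A,C,G,T,N")
    if not seq:
        raise ValueError("empty sequence")
    return seq


def encode_binary(seq: str) -> EncodedMatrix:
    """One-hot encode each base over channels (A,C,G,T,N); N rows are all-zero.

    A maps to (1,0,0,0,0), C to (0,1,0,0,0), G to (0,0,1,0,0), T to
    (0,0,0,1,0), and the ambiguous N to (0,0,0,0,0), giving 5L features for a
    length-L window.
    """
    seq = _check_alphabet(seq)
    out = np.zeros((len(seq), 5))
    for i, s in enumerate(seq):
        if s != "N":
            out[i, BE_ORDER.index(s)] = 1.0
    return EncodedMatrix(out, "BE")


def _kmer_index(k: int) -> dict[str, int]:
    return {
        "".join(t): i
        for i, t in enumerate(itertools.product(KMER_ORDER, repeat=k))
    }


_KMER_INDEX = {2: _kmer_index(2), 3: _kmer_index(3)}


def encode_kmer_onehot(seq: str, k: int) -> EncodedMatrix:
    """Positionally one-hot encode the L-k+1 overlapping k-mers.

    k=2 (dinucleotide composition, DNC) yields (L-1, 25); k=3 (trinucleotide
    composition, TNC) yields (L-2, 125). Channel order is frozen (see module
    docstring).
    """
    if k not in (2, 3):
        raise ValueError(f"k must be 2 or 3, got {k}")
    seq = _check_alphabet(seq)
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    index = _KMER_INDEX[k]
    n = len(seq) - k + 1
    out = np.zeros((n, 5**k))
    for i in range(n):
        out[i, index[seq[i : i + k]]] = 1.0
    return EncodedMatrix(out, "DNC" if k == 2 else "TNC")


def encode_ncp(seq: str) -> EncodedMatrix:
    """Encode each base by its three chemical-property bits (x, y, z)."""
    seq = _check_alphabet(seq)
    out = np.array([CHEMICAL_PROPERTY_TABLE[s] for s in seq], dtype=float)
    return EncodedMatrix(out, "NCP")


def cumulative_density(seq: str) -> np.ndarray:
    """d_i = (occurrences of seq[i] among positions 0..i) / (i + 1).

    The running within-prefix frequency of each position's own base; d_0 is
    always 1 and every d_i lies in (0, 1].
    """
    counts: dict[str, int] = {}
    out = np.empty(len(seq))
    for i, s in enumerate(seq):
        counts[s] = counts.get(s, 0) + 1
        out[i] = counts[s] / (i + 1)
    return out


def encode_ncpnf(seq: str, pad_to_five: bool = False) -> EncodedMatrix:
    """Chemical-property bits plus the cumulative nucleotide density channel.

    Rows are (x_i, y_i, z_i, d_i). ``pad_to_five`` appends an all-zero fifth
    channel for strict 5-channel shape parity with the per-base one-hot.
    """
    seq = _check_alphabet(seq)
    ncp = np.array([CHEMICAL_PROPERTY_TABLE[s] for s in seq], dtype=float)
    dens = cumulative_density(seq)[:, None]
    out = np.hstack([ncp, dens])
    if pad_to_five:
        out = np.hstack([out, np.zeros((len(seq), 1))])
    return EncodedMatrix(out, "NCPNF")


# --- multivariate mutual information -----------------------------------------

#: the 15 unordered 2-tuples over {A,C,G,T,N}
T2: tuple[str, ...] = tuple(
    "".join(t) for t in itertools.combinations_with_replacement("ACGTN", 2)
)

#: the complete 35-member unordered 3-tuple multiset over {A,C,G,T,N}
T3: tuple[str, ...] = tuple(
    "".join(t) for t in itertools.combinations_with_replacement("ACGTN", 3)
)

_SYMBOL_RANK = {s: i for i, s in enumerate("ACGTN")}


def _canonical(tup: str) -> str:
    return "".join(sorted(tup, key=_SYMBOL_RANK.__getitem__))


def _xlogy_term(f: float, num: float, den: float) -> float:
    """f * ln(num/den), defined as 0 when any frequency involved is 0."""
    if f == 0.0 or num == 0.0 or den == 0.0:
        return 0.0
    return f * math.log(num / den)


def encode_mmi(seq: str) -> EncodedMatrix:
    """55 multivariate mutual-information features as a (55, 1) column vector.

    The vector concatenates

    * 5 mononucleotide frequencies f(a) = count(a)/L, in order A,C,G,T,N;
    * 15 pairwise terms I2(a,b) = f2(a,b) ln[f2(a,b) / (f(a) f(b))] over the
      unordered pair set T2, where f2 counts unordered adjacent pairs over the
      L-1 windows;
    * 35 triple terms I3(a,b,c) = I2(a,b) − f3(a,b,c) ln[f3(a,b,c) f(c) /
      (f2(a,c) f2(b,c))] over the complete unordered triple multiset T3, with
      f3 counting unordered adjacent triples over the L-2 windows.

    Any logarithmic term touching a zero frequency is defined as 0.
    """
    seq = _check_alphabet(seq)
    L = len(seq)
    f1 = {s: seq.count(s) / L for s in "ACGTN"}

    f2: dict[str, float] = dict.fromkeys(T2, 0.0)
    for i in range(L - 1):
        f2[_canonical(seq[i : i + 2])] += 1.0
    if L > 1:
        for key in f2:
            f2[key] /= L - 1

    f3: dict[str, float] = dict.fromkeys(T3, 0.0)
    for i in range(L - 2):
        f3[_canonical(seq[i : i + 3])] += 1.0
    if L > 2:
        for key in f3:
            f3[key] /= L - 2

    def i2(a: str, b: str) -> float:
        fab = f2[_canonical(a + b)]
        return _xlogy_term(fab, fab, f1[a] * f1[b])

    features = [f1[s] for s in "ACGTN"]
    features += [i2(t[0], t[1]) for t in T2]
    for t in T3:
        a, b, c = t
        fabc = f3[t]
        fac = f2[_canonical(a + c)]
        fbc = f2[_canonical(b + c)]
        features.append(i2(a, b) - _xlogy_term(fabc, fabc * f1[c], fac * fbc))

    return EncodedMatrix(np.array(features)[:, None], "MMI")


_ENCODERS = {
    "BE": encode_binary,
    "DNC": lambda s: encode_kmer_onehot(s, 2),
    "TNC": lambda s: encode_kmer_onehot(s, 3),
    "NCP": encode_ncp,
    "NCPNF": encode_ncpnf,
    "MMI": encode_mmi,
}


def encode_sequence(seq: str, scheme: str) -> EncodedMatrix:
    """Dispatch to the encoder named by ``scheme`` (case-insensitive)."""
    scheme = scheme.upper()
    if scheme not in _ENCODERS:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    return _ENCODERS[scheme](seq)


def encode_dataset(
    ds: LabeledDataset, scheme: str
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every record, returning (n, positions, channels) X and labels y."""
    if len(ds) == 0:
        raise ValueError("cannot encode an empty dataset")
    lengths = {r.length for r in ds}
    if len(lengths) > 1:
        raise ValueError(f"mixed sequence lengths {sorted(lengths)}")
    X = np.stack([encode_sequence(r.seq, scheme).values for r in ds])
    y = np.array(ds.labels(), dtype=float)
    return X, y


def encoded_to_frame(X: np.ndarray, scheme: str):
    """Flatten an encoded stack to a DataFrame (scheme_pos<i>_ch<j> columns)."""
    import pandas as pd

    n, p, c = X.shape
    cols = [f"{scheme}_pos{i}_ch{j}" for i in range(p) for j in range(c)]
    return pd.DataFrame(X.reshape(n, p * c), columns=cols)
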