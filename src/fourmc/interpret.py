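"""Model interpretation: in silico saturation mutagenesis and saliency maps.

Mutagenesis substitutes every position of every window with each of the five
symbols A, C, G, T, N, re-encodes, re-predicts, and records the absolute
change in the predicted 4mC probability; the map is the element-wise mean
over the dataset. A model that keys on a central methylation context shows a
peak around the central C.

The saliency map is a gradient x input attribution: the gradient of the
pre-sigmoid score with respect to the encoded input is multiplied
element-wise by the encoding, channel-summed per position, and aggregated
into per-dinucleotide cells — the score of the 2-mer starting at position i
is the sum of the importances of its two member bases, accumulated into the
cell of the dinucleotide actually observed there, then averaged over records.
Differentiating the logit rather than the probability avoids vanishing
attribution on confidently classified windows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .encoders import KMER_ORDER, encode_sequence, scheme_shape
from .seqio import LabeledDataset

MUTATION_SYMBOLS = "ACGTN"

#: frozen dinucleotide axis of the saliency map (matches the DNC channel order)
DINUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(t) for t in itertools.product(KMER_ORDER, repeat=2))

_BATCH = 512


@dataclass
class MutagenesisMap:
    """(L positions x 5 symbols) mean absolute prediction differences."""

    values: np.ndarray
    n_sequences: int
    symbols: str = MUTATION_SYMBOLS

    def position_profile(self) -> np.ndarray:
        """Mean over substitution symbols: one sensitivity value per position."""
        return self.values.mean(axis=1)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=list(self.symbols)).rename_axis(
            "position").to_csv(path)


@dataclass
class SaliencyMap:
    """((L-1) 2-mer positions x 25 dinucleotides) mean attribution scores."""

    values: np.ndarray
    position_scores: np.ndarray  # length L-1: mean observed-2-mer score per position
    n_sequences: int
    dinucleotides: tuple[str, ...] = DINUCLEOTIDES

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=list(self.dinucleotides)).rename_axis(
            "position").to_csv(path)


def _positive_probs(model, X: np.ndarray) -> np.ndarray:
    p = model.predict_proba(X)
    p = np.asarray(p)
    return p[:, 1] if p.ndim == 2 else p


def _select(ds: LabeledDataset, positives_only: bool) -> list[str]:
    seqs = [r.seq for r in ds if r.label == 1 or not positives_only]
    if not seqs:
        raise ValueError("no records to interpret (dataset empty after filtering)")
    return seqs


def mutagenesis_map(model, ds: LabeledDataset, scheme: str,
                    positives_only: bool = False) -> MutagenesisMap:
    """Systematic substitution map, averaged over the supplied records.

    Entry (i, a) is the mean of |p(mutated) - p(original)| over records, where
    the mutation writes symbol ``a`` at position i; substituting a record's
    own symbol contributes 0 by construction.
    """
    if not hasattr(model, "predict_proba"):
        raise TypeError("model must expose predict_proba (a trained classifier)")
    seqs = _select(ds, positives_only)
    L = len(seqs[0])
    acc = np.zeros((L, len(MUTATION_SYMBOLS)))
    for seq in seqs:
        p_orig = _positive_probs(
            model, encode_sequence(seq, scheme).values[None])[0]
        mutants, cells = [], []
        for i in range(L):
            for a_idx, a in enumerate(MUTATION_SYMBOLS):
                if seq[i] == a:
                    continue
                mutants.append(seq[:i] + a + seq[i + 1:])
                cells.append((i, a_idx))
        X = np.stack([encode_sequence(m, scheme).values for m in mutants])
        diffs = np.abs(_positive_probs(model, X) - p_orig)
        for (i, a_idx), d in zip(cells, diffs):
            acc[i, a_idx] += d
    return MutagenesisMap(values=acc / len(seqs), n_sequences=len(seqs))


def _per_base_importance(imp: np.ndarray, L: int) -> np.ndarray:
    """Map per-input-position gradient x input importance to per-base scores.

    Per-base encodings pass through unchanged; k-mer positional encodings
    spread each window's importance over its member bases.
    """
    n, P = imp.shape
    k = L - P + 1
    if k == 1:
        return imp
    base = np.zeros((n, L))
    for j in range(k):
        base[:, j : j + P] += imp
    return base


def saliency_map(model, ds: LabeledDataset, scheme: str,
                 positives_only: bool = False) -> SaliencyMap:
    """Gradient x input attribution binned by observed dinucleotide.

    Requires an encoding whose rows index sequence positions; the global MMI
    vector has no such gradient path and is rejected.
    """
    scheme = scheme.upper()
    if scheme == "MMI":
        raise ValueError(
            "scheme 'MMI' has no gradient path back to sequence positions; "
            "use a positional encoding (BE, DNC, TNC, NCP, NCPNF)")
    if not hasattr(model, "input_gradient"):
        raise TypeError("model must expose input_gradient (a trained classifier)")
    seqs = _select(ds, positives_only)
    L = len(seqs[0])
    n2 = L - 1
    kmer_index = {d: i for i, d in enumerate(DINUCLEOTIDES)}
    acc = np.zeros((n2, len(DINUCLEOTIDES)))
    pos_acc = np.zeros(n2)
    for start in range(0, len(seqs), _BATCH):
        chunk = seqs[start : start + _BATCH]
        X = np.stack([encode_sequence(s, scheme).values for s in chunk])
        grad = model.input_gradient(X)
        imp = (grad * X).sum(axis=2)  # (n, input positions)
        P = imp.shape[1]
        if P == n2:
            scores = imp  # input positions already index 2-mers
        else:
            base = _per_base_importance(imp, L)
            scores = base[:, :-1] + base[:, 1:]
        for s_i, seq in zip(scores, chunk):
            for i in range(n2):
                acc[i, kmer_index[seq[i : i + 2]]] += s_i[i]
                pos_acc[i] += s_i[i]
    n = len(seqs)
    return SaliencyMap(values=acc / n, position_scores=pos_acc / n, n_sequences=n)


def render_heatmap(attribution, path, title: str | None = None) -> None:
    """Write a position x symbol heat map (PNG or SVG by file extension)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    values = attribution.values
    if values.size == 0 or attribution.n_sequences == 0:
        raise ValueError("cannot render an empty attribution map")
    if isinstance(attribution, MutagenesisMap):
        ylabels = list(attribution.symbols)
    else:
        ylabels = list(attribution.dinucleotides)
    fig, ax = plt.subplots(
        figsize=(10, max(2.0, 0.22 * len(ylabels))), constrained_layout=True)
    im = ax.imshow(values.T, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xlabel("position")
    ax.set_yticks(range(len(ylabels)))
    ax.set_yticklabels(ylabels, fontsize=6 if len(ylabels) > 10 else 10)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
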