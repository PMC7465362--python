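"""Synthetic labeled 41-nt window datasets with a tunable planted motif.

The generator emulates the shape of 4mC benchmark sets: balanced positive and
negative classes of fixed-length windows with a central C. Class signal comes
from a short motif planted at a fixed offset from the center with probability
``p_pos`` in positives and ``p_neg`` in negatives; p_pos = 1, p_neg = 0 gives
classes separable by a substring test, p_pos = p_neg gives identically
distributed classes (a no-signal null). Background bases are i.i.d. uniform
over A,C,G,T with a small N admixture so that every encoder's N path is
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import LabeledDataset, SequenceRecord

_DEFAULT_BACKGROUND = {"A": 0.2475, "C": 0.2475, "G": 0.2475, "T": 0.2475, "N": 0.01}


@dataclass
class SyntheticSpec:
    """Study conditions for one generated dataset.

    ``motif_offset`` places the motif's first base relative to the central
    position (offset 0 starts the motif on the central C itself, so the
    default "CC" covers the center and its right neighbor).
    """

    n_per_class: int = 100
    length: int = 41
    motif: str = "CC"
    motif_offset: int = 0
    p_pos: float = 0.9
    p_neg: float = 0.1
    background: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BACKGROUND))
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.length < 1 or self.length % 2 == 0:
            raise ValueError(f"length must be odd and positive, got {self.length}")
        if not 0.0 <= self.p_neg <= self.p_pos <= 1.0:
            raise ValueError(
                f"need 0 <= p_neg <= p_pos <= 1, got p_neg={self.p_neg}, "
                f"p_pos={self.p_pos}")
        if set(self.motif) - set("ACGT"):
            raise ValueError("motif must be over A,C,G,T")
        start = self.center + self.motif_offset
        if start < 0 or start + len(self.motif) > self.length:
            raise ValueError(
                f"motif of length {len(self.motif)} at offset {self.motif_offset} "
                f"overruns the {self.length}-nt window")
        if start <= self.center < start + len(self.motif):
            if self.motif[self.center - start] != "C":
                raise ValueError(
                    "a motif overlapping the central position must carry 'C' "
                    "there (the central C is enforced in every record)")
            if len(self.motif) == 1:
                raise ValueError(
                    "motif 'C' at the central position is present in every "
                    "record and cannot carry class signal")
        total = sum(self.background.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"background probabilities sum to {total}, expected 1")

    @property
    def center(self) -> int:
        return (self.length - 1) // 2

    @property
    def motif_start(self) -> int:
        return self.center + self.motif_offset


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw ``n_per_class`` positives and negatives; deterministic per seed.

    Each window is drawn i.i.d. from the background and the central base is
    forced to C. With the class's planting probability the motif is then
    written at its fixed site; otherwise the site is guaranteed NOT to spell
    the motif (chance matches at the site are redrawn), so motif presence at
    the site is exactly Bernoulli(p) per class and p = 1 vs q = 0 yields
    classes separable by a single substring test at the site. Occurrences of
    the motif elsewhere in the window remain possible, as in real sequence.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = np.array(list(spec.background.keys()))
    probs = np.array(list(spec.background.values()))
    start, end = spec.motif_start, spec.motif_start + len(spec.motif)
    free = [j for j in range(start, end) if j != spec.center]
    records = []
    for label, p_plant in ((1, spec.p_pos), (0, spec.p_neg)):
        for i in range(spec.n_per_class):
            chars = rng.choice(symbols, size=spec.length, p=probs)
            chars[spec.center] = "C"
            if rng.random() < p_plant:
                chars[start:end] = list(spec.motif)
            else:
                while "".join(chars[start:end]) == spec.motif:
                    chars[free] = rng.choice(symbols, size=len(free), p=probs)
            prefix = "pos" if label else "neg"
            records.append(SequenceRecord(
                id=f"{prefix}_{i}", seq="".join(chars), label=label))
    ds = LabeledDataset(records, name="synthetic")
    ds.validate()
    return ds


def motif_presence_rate(ds: LabeledDataset, spec: SyntheticSpec, label: int) -> float:
    """Fraction of records of ``label`` carrying the motif at its planting site."""
    hits = total = 0
    for r in ds:
        if r.label != label:
            continue
        total += 1
        hits += r.seq[spec.motif_start : spec.motif_start + len(spec.motif)] == spec.motif
    if total == 0:
        raise ValueError(f"no records with label {label}")
    return hits / total
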