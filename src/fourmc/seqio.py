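"""Reading, validating, writing, filtering and splitting labeled 41-nt windows.

The benchmark layout this package consumes is a pair of FASTA files — one of
putative 4mC-positive windows, one of negatives — where every record is a
fixed-length window (41 nt by default) over the alphabet {A, C, G, T, N} with
the assayed cytosine at the central position (index 20 for L = 41, 0-based).
Labels travel outside the FASTA: one file per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import train_test_split

ALPHABET = frozenset("ACGTN")
DEFAULT_LENGTH = 41


class ValidationError(ValueError):
    """A sequence record violates the window contract (length/alphabet/central C)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length DNA window with a binary 4mC label (1 = 4mC)."""

    id: str
    seq: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def center(self) -> int:
        return (len(self.seq) - 1) // 2


def validate_record(
    rec: SequenceRecord,
    length: int = DEFAULT_LENGTH,
    require_central_c: bool = True,
) -> None:
    """Raise :class:`ValidationError` unless ``rec`` is a valid window.

    Checks length, alphabet and (unless disabled) that the central base is C.
    """
    if len(rec.seq) != length:
        raise ValidationError(
            f"record {rec.id!r}: expected length {length}, got {len(rec.seq)}"
        )
    bad = set(rec.seq) - ALPHABET
    if bad:
        raise ValidationError(
            f"record {rec.id!r}: invalid symbols {sorted(bad)} (alphabet is A,C,G,T,N)"
        )
    if require_central_c and rec.seq[rec.center] != "C":
        raise ValidationError(
            f"record {rec.id!r}: central base at position {rec.center} is "
            f"{rec.seq[rec.center]!r}, expected 'C'"
        )


@dataclass
class LabeledDataset:
    """An ordered collection of equal-length :class:`SequenceRecord` objects."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def length(self) -> int:
        """Common window length L of all records."""
        if not self.records:
            raise ValueError("empty dataset has no window length")
        return self.records[0].length

    def label_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for r in self.records:
            counts[r.label] += 1
        return counts

    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def subset(self, indices: Iterable[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices],
            name=name if name is not None else self.name,
        )

    def validate(self, length: int | None = None, require_central_c: bool = True) -> None:
        if not self.records:
            return
        L = length if length is not None else self.records[0].length
        for r in self.records:
            validate_record(r, length=L, require_central_c=require_central_c)


def read_fasta(
    path: str | Path,
    label: int,
    length: int = DEFAULT_LENGTH,
    require_central_c: bool = True,
    validate: bool = True,
) -> LabeledDataset:
    """Read one FASTA file into a dataset, assigning ``label`` to every record.

    Sequences are uppercased. Validation (length, alphabet, central C) reports
    the offending record id; set ``validate=False`` to bypass entirely, or
    ``require_central_c=False`` to relax only the central-C check.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: not FASTA — line {lineno} does not start "
                        f"a '>' header")
                break
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rec = SequenceRecord(id=entry.id, seq=str(entry.seq).upper(), label=label)
        if validate:
            validate_record(rec, length=length, require_central_c=require_central_c)
        records.append(rec)
    return LabeledDataset(records, name=path.stem)


def read_fasta_pair(
    positive_path: str | Path,
    negative_path: str | Path,
    **kwargs,
) -> LabeledDataset:
    """Read the positive/negative two-FASTA benchmark layout into one dataset."""
    pos = read_fasta(positive_path, label=1, **kwargs)
    neg = read_fasta(negative_path, label=0, **kwargs)
    return LabeledDataset(pos.records + neg.records, name="merged")


def write_fasta(ds: LabeledDataset, path: str | Path) -> None:
    """Write records as single-line-body FASTA (labels are not embedded)."""
    entries = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in ds.records
    ]
    with open(path, "w") as fh:
        SeqIO.write(entries, fh, "fasta-2line")


def write_tsv(ds: LabeledDataset, path: str | Path) -> None:
    """Export as TSV with columns id, sequence, label."""
    with open(path, "w") as fh:
        fh.write("id\tsequence\tlabel\n")
        for r in ds.records:
            fh.write(f"{r.id}\t{r.seq}\t{r.label}\n")


def split_dataset(
    ds: LabeledDataset,
    train_fraction: float,
    seed: int,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/holdout split (e.g. the conventional 75/25 partition).

    Deterministic for a fixed seed; the two outputs are disjoint and their
    union is the input.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    counts = ds.label_counts()
    if min(counts.values()) < 2:
        raise ValueError(
            f"need at least 2 records per class to split, have {counts}"
        )
    idx = list(range(len(ds)))
    try:
        train_idx, test_idx = train_test_split(
            idx,
            train_size=train_fraction,
            random_state=seed,
            stratify=ds.labels(),
            shuffle=True,
        )
    except ValueError:
        # either side smaller than the class count: stratification is
        # impossible, fall back to a plain shuffled split
        train_idx, test_idx = train_test_split(
            idx, train_size=train_fraction, random_state=seed, shuffle=True)
    return (
        ds.subset(sorted(train_idx), name=f"{ds.name}/train"),
        ds.subset(sorted(test_idx), name=f"{ds.name}/holdout"),
    )


def ungapped_identity(a: str, b: str) -> float:
    """Fraction of matching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def greedy_redundancy_filter(
    ds: LabeledDataset, identity_threshold: float
) -> LabeledDataset:
    """Drop near-duplicate records by a greedy single-pass identity scan.

    A record is dropped when its ungapped identity to any already-retained
    record is >= ``identity_threshold``; input order is preserved. This is a
    deliberately naive plumbing filter and makes no attempt to replicate
    clustering tools such as CD-HIT-EST.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    retained: list[SequenceRecord] = []
    for rec in ds.records:
        if all(
            ungapped_identity(rec.seq, kept.seq) < identity_threshold
            for kept in retained
        ):
            retained.append(rec)
    return LabeledDataset(retained, name=ds.name)
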