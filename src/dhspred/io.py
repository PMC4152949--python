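"""Reading, validating and writing DNA sequences and two-class datasets.

The unit of data is a :class:`NucleotideSequence` (an identifier plus a
validated A/C/G/T string) and an ordered :class:`LabeledDataset` pairing
sequences with ``positive`` (DHS) / ``negative`` (non-DHS) labels.  FASTA is
the only sequence format; parsing is delegated to Biopython.

Validation policy
-----------------
* lowercase residues are accepted and upper-cased (soft-masking discarded);
* ``N`` is rejected by default; ``drop_ambiguous=True`` silently drops such
  records and logs how many were removed;
* any residue outside ``{A,C,G,T,N}`` raises
  :class:`~dhspred.exceptions.SequenceValidationError` naming the record and
  the 1-based offending position;
* sequences are used exactly as given — no reverse-complement
  canonicalization.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

from .exceptions import DatasetError, FastaParseError, SequenceValidationError

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = (POSITIVE, NEGATIVE)

_VALID = set("ACGT")
_AMBIGUOUS = set("N")


@dataclass(frozen=True)
class NucleotideSequence:
    """One validated DNA sequence over {A,C,G,T}.

    ``residues`` is upper-cased on construction; at least two bases are
    required so that the sequence contains at least one dinucleotide.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if len(residues) < 2:
            raise SequenceValidationError(
                f"sequence {self.id!r}: length {len(residues)} < 2 "
                "(need at least one dinucleotide)"
            )
        for pos, base in enumerate(residues, start=1):
            if base not in _VALID:
                raise SequenceValidationError(
                    f"sequence {self.id!r}: invalid residue {base!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledDataset:
    """An ordered collection of sequences with parallel binary labels.

    ``labels[i]`` is ``"positive"``, ``"negative"`` or ``None`` (unlabeled,
    e.g. prediction input).  Sequence order is meaningful and preserved by
    every operation in the package.
    """

    sequences: tuple[NucleotideSequence, ...]
    labels: tuple[Optional[str], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise DatasetError(
                f"dataset {self.name!r}: {len(self.sequences)} sequences but "
                f"{len(self.labels)} labels"
            )
        for lab in self.labels:
            if lab is not None and lab not in LABELS:
                raise DatasetError(f"dataset {self.name!r}: invalid label {lab!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[tuple[NucleotideSequence, Optional[str]]]:
        return iter(zip(self.sequences, self.labels))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sequences)

    @property
    def n_positive(self) -> int:
        return sum(1 for lab in self.labels if lab == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for lab in self.labels if lab == NEGATIVE)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            sequences=tuple(self.sequences[i] for i in indices),
            labels=tuple(self.labels[i] for i in indices),
            name=self.name if name is None else name,
        )


def _clean_residues(raw: str) -> str:
    """Strip whitespace inside sequence lines; Biopython already joins lines."""
    return "".join(raw.split())


def read_fasta(
    path: str | Path,
    label: Optional[str] = None,
    drop_ambiguous: bool = False,
    name: str | None = None,
) -> LabeledDataset:
    """Read a FASTA file into a :class:`LabeledDataset`.

    Parameters
    ----------
    path
        FASTA file (wrapped or unwrapped lines).
    label
        ``"positive"``, ``"negative"`` or ``None``; applied to every record.
    drop_ambiguous
        If True, records containing ``N`` are dropped (count logged) instead
        of raising.
    """
    path = Path(path)
    if label is not None and label not in LABELS:
        raise DatasetError(f"invalid label {label!r}")
    sequences: list[NucleotideSequence] = []
    n_dropped = 0
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, AssertionError) as exc:  # Biopython parse failure
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        # distinguish "no FASTA records" from an empty dataset on purpose:
        # an empty or non-FASTA file is almost always a caller mistake
        with open(path) as fh:
            first = fh.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(
                f"{path}: line 1 does not start with '>' — not FASTA"
            )
    for rec in records:
        residues = _clean_residues(str(rec.seq)).upper()
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        ambiguous = _AMBIGUOUS.intersection(residues)
        if ambiguous:
            if drop_ambiguous:
                n_dropped += 1
                continue
            pos = next(
                i for i, b in enumerate(residues, start=1) if b in _AMBIGUOUS
            )
            raise SequenceValidationError(
                f"sequence {rec.id!r}: ambiguous residue 'N' at position {pos} "
                "(use drop_ambiguous to remove such records)"
            )
        sequences.append(NucleotideSequence(id=rec.id, residues=residues))
    if n_dropped:
        logger.info("%s: dropped %d record(s) containing N", path, n_dropped)
    return LabeledDataset(
        sequences=tuple(sequences),
        labels=(label,) * len(sequences),
        name=name if name is not None else path.stem,
    )


def write_fasta(data: LabeledDataset | Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences to FASTA, one unwrapped line per record."""
    seqs = data.sequences if isinstance(data, LabeledDataset) else tuple(data)
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def merge_datasets(pos: LabeledDataset, neg: LabeledDataset, name: str = "") -> LabeledDataset:
    """Concatenate an all-positive and an all-negative dataset, positives first.

    Raises :class:`~dhspred.exceptions.DatasetError` if either operand carries
    a wrong label or the two share sequence identifiers.
    """
    if any(lab != POSITIVE for lab in pos.labels):
        raise DatasetError("first operand must be all-positive")
    if any(lab != NEGATIVE for lab in neg.labels):
        raise DatasetError("second operand must be all-negative")
    collisions = sorted(set(pos.ids) & set(neg.ids))
    if collisions:
        raise DatasetError(
            "duplicate sequence identifiers across classes: " + ", ".join(collisions)
        )
    return LabeledDataset(
        sequences=pos.sequences + neg.sequences,
        labels=pos.labels + neg.labels,
        name=name or f"{pos.name}+{neg.name}",
    )


def read_manifest(path: str | Path, drop_ambiguous: bool = False) -> LabeledDataset:
    """Read a two-column TSV manifest ``path<TAB>label`` into one dataset.

    Paths are resolved relative to the manifest's directory.  Positives are
    ordered before negatives, preserving manifest order within each class.
    """
    path = Path(path)
    pos_parts: list[LabeledDataset] = []
    neg_parts: list[LabeledDataset] = []
    with open(path) as fh:
        for line_no, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) != 2:
                raise DatasetError(f"{path}:{line_no}: expected 2 columns, got {len(row)}")
            fasta_path, label = row[0].strip(), row[1].strip()
            if label not in LABELS:
                raise DatasetError(f"{path}:{line_no}: invalid label {label!r}")
            part = read_fasta(
                path.parent / fasta_path, label=label, drop_ambiguous=drop_ambiguous
            )
            (pos_parts if label == POSITIVE else neg_parts).append(part)

    def _concat(parts: list[LabeledDataset], label: str) -> LabeledDataset:
        seqs: tuple[NucleotideSequence, ...] = ()
        for p in parts:
            seqs = seqs + p.sequences
        return LabeledDataset(seqs, (label,) * len(seqs), name=label)

    return merge_datasets(
        _concat(pos_parts, POSITIVE), _concat(neg_parts, NEGATIVE), name=path.stem
    )
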