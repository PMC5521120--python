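"""Reading, writing and validation of protein sequences and class labels.

The descriptor engines operate on the 20 standard one-letter residue codes
only, so every sequence entering the package passes through
:func:`canonicalize`.  Two policies are supported: ``strict`` (any other
character is an error) and ``skip_unknown`` (ambiguity codes such as X, B, Z,
U, J, O and gap characters are removed and counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

CANONICALIZE_POLICIES = ("strict", "skip_unknown")


class SequenceError(ValueError):
    """Raised for malformed FASTA input, alphabet violations or label errors."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with a unique identifier.

    The sequence is expected to be canonical (uppercase, 20-letter alphabet);
    use :func:`canonicalize` before constructing records from raw input.
    """

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Sequence records paired one-to-one with binary class labels.

    ``labels[i]`` is 1 for the positive class (enzyme) and 0 otherwise, and
    refers to ``records[i]``.
    """

    records: list[SequenceRecord]
    labels: np.ndarray
    class_names: tuple[str, str] = ("non_enzyme", "enzyme")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != self.labels.size:
            raise SequenceError(
                f"{len(self.records)} records but {self.labels.size} labels"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise SequenceError("labels must be binary (0/1)")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def require_both_classes(self) -> None:
        """Training mode precondition: at least one member of each class."""
        if self.labels.size == 0 or len(set(self.labels.tolist())) < 2:
            raise SequenceError(
                "training requires at least one instance of each class"
            )


def canonicalize(sequence: str, policy: str = "strict") -> str:
    """Uppercase a raw sequence and enforce the 20-letter alphabet.

    Under ``strict`` any out-of-alphabet character raises with its 1-based
    position; under ``skip_unknown`` such characters are removed and the
    removal count is logged.  The function is idempotent.
    """
    if policy not in CANONICALIZE_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {CANONICALIZE_POLICIES}")
    upper = sequence.upper()
    if policy == "strict":
        for pos, ch in enumerate(upper, start=1):
            if ch not in _AA_SET:
                raise SequenceError(
                    f"non-standard residue {ch!r} at position {pos} (strict policy)"
                )
        return upper
    kept = [ch for ch in upper if ch in _AA_SET]
    n_removed = len(upper) - len(kept)
    if n_removed:
        logger.warning("canonicalize: removed %d non-standard character(s)", n_removed)
    return "".join(kept)


def read_fasta(path: str | Path, policy: str = "strict") -> list[SequenceRecord]:
    """Read a FASTA file into canonical :class:`SequenceRecord` objects.

    Headers are truncated at the first whitespace to form ids; multi-line
    bodies are joined.  Duplicate ids and empty files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if not rid:
            raise SequenceError(f"{path}: malformed header (empty id)")
        if rid in seen:
            raise SequenceError(f"{path}: duplicate id {rid!r}")
        seen.add(rid)
        seq = canonicalize(str(entry.seq), policy=policy)
        if not seq:
            raise SequenceError(f"{path}: record {rid!r} has an empty sequence")
        records.append(SequenceRecord(id=rid, sequence=seq))
    if not records:
        raise SequenceError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrapped bodies)."""
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(Path(path)), "fasta")


def read_labels(
    path: str | Path,
    delimiter: str = "\t",
    positive_labels: Sequence[str] = ("1", "enzyme"),
    negative_labels: Sequence[str] = ("0", "non_enzyme", "non-enzyme"),
) -> dict[str, int]:
    """Parse a headerless two-column (id, label) table into ``{id: 0/1}``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pos = {str(p).lower() for p in positive_labels}
    neg = {str(n).lower() for n in negative_labels}
    labels: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split(delimiter)
        if len(parts) != 2:
            raise SequenceError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        rid, raw = parts[0].strip(), parts[1].strip().lower()
        if rid in labels:
            raise SequenceError(f"{path}:{lineno}: duplicate label for id {rid!r}")
        if raw in pos:
            labels[rid] = 1
        elif raw in neg:
            labels[rid] = 0
        else:
            raise SequenceError(
                f"{path}:{lineno}: labels must be binary; got {raw!r} "
                f"(accepted: {sorted(pos)} / {sorted(neg)})"
            )
    return labels


def load_labeled_dataset(
    fasta: str | Path,
    labels: str | Path,
    delimiter: str = "\t",
    policy: str = "strict",
    positive_labels: Sequence[str] = ("1", "enzyme"),
    training: bool = True,
) -> LabeledDataset:
    """Join a FASTA file with a label table into a :class:`LabeledDataset`.

    Ids must match exactly.  In training mode an unlabeled record is an
    error; labels for unknown ids are always an error.
    """
    records = read_fasta(fasta, policy=policy)
    table = read_labels(labels, delimiter=delimiter, positive_labels=positive_labels)
    ids = {r.id for r in records}
    unknown = sorted(set(table) - ids)
    if unknown:
        raise SequenceError(f"labels for unknown id(s): {', '.join(unknown)}")
    missing = [r.id for r in records if r.id not in table]
    if missing and training:
        raise SequenceError(f"unlabeled record(s): {', '.join(missing)}")
    kept = [r for r in records if r.id in table]
    y = np.array([table[r.id] for r in kept], dtype=int)
    ds = LabeledDataset(records=kept, labels=y)
    if training:
        ds.require_both_classes()
    return ds


def write_labels(dataset: LabeledDataset, path: str | Path, delimiter: str = "\t") -> None:
    """Write the dataset's labels as a headerless (id, 0/1) table."""
    lines = [f"{r.id}{delimiter}{int(l)}" for r, l in zip(dataset.records, dataset.labels)]
    Path(path).write_text("\n".join(lines) + "\n")
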