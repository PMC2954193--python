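"""Protein FASTA input/output and residue sanitization.

Every downstream encoder assumes sequences over the canonical 20-letter
amino-acid alphabet, so all parsing funnels through :func:`sanitize`.
Record order is preserved everywhere: cross-validation fold indices are
only reproducible if the dataset order is.
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical residue order used for every feature index in the package.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Characters treated as formatting noise and silently stripped.
_FORMATTING = set(" \t\r\n0123456789-.*")

SANITIZE_POLICIES = ("strict-drop", "reject")


class SequenceError(ValueError):
    """Raised for malformed or invalid sequence input."""


def sanitize(raw: str, policy: str = "strict-drop") -> str:
    """Normalize a raw residue string to the canonical 20-letter alphabet.

    Uppercases, strips whitespace/digits/gap characters, then handles any
    remaining non-standard letters (B, Z, J, X, U, O, ...) according to
    ``policy``:

    ``strict-drop``
        remove them and log a warning with per-character counts (default);
    ``reject``
        raise :class:`SequenceError` on the first non-standard letter.

    Raises if the result is empty or the policy name is unknown.
    Idempotent: ``sanitize(sanitize(x)) == sanitize(x)``.
    """
    if policy not in SANITIZE_POLICIES:
        raise SequenceError(f"unknown sanitization policy: {policy!r}")
    kept: list[str] = []
    dropped: Counter[str] = Counter()
    for ch in raw:
        if ch in _FORMATTING:
            continue
        up = ch.upper()
        if up in AA_INDEX:
            kept.append(up)
        elif policy == "reject":
            raise SequenceError(f"non-standard residue {ch!r} under 'reject' policy")
        else:
            dropped[up] += 1
    if dropped:
        detail = ", ".join(f"{aa}x{n}" for aa, n in sorted(dropped.items()))
        logger.warning("dropped %d non-standard residue(s): %s", sum(dropped.values()), detail)
    result = "".join(kept)
    if not result:
        raise SequenceError("sequence empty after sanitization")
    return result


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence: identifier plus canonical residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-canonical residues {sorted(bad)}; "
                "run sanitize() first"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n(self) -> int:
        """Sequence length N."""
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Ordered sequences with parallel binary labels (1 = positive class)."""

    sequences: list[ProteinSequence]
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise SequenceError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if self.labels.size and not set(np.unique(self.labels)) <= {0, 1}:
            raise SequenceError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def require_two_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise SequenceError("training requires at least one member of each class")


def read_fasta(source, policy: str = "strict-drop") -> list[ProteinSequence]:
    """Read a FASTA file or text stream into :class:`ProteinSequence` records.

    The id is the header token up to the first whitespace; the remainder is
    kept as ``description``. Residues are sanitized under ``policy``. File
    order is preserved. Duplicate ids, empty records, and empty files are
    errors.
    """
    if isinstance(source, (str, Path)):
        handle: io.TextIOBase = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        records: list[ProteinSequence] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if not str(rec.seq):
                raise SequenceError(f"record {rec.id!r} has an empty sequence")
            if rec.id in seen:
                raise SequenceError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(
                ProteinSequence(id=rec.id, residues=sanitize(str(rec.seq), policy), description=desc)
            )
        if not records:
            raise SequenceError("no records found in FASTA input")
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[ProteinSequence], sink) -> None:
    """Write records as standard FASTA with 60-column-wrapped sequence lines."""
    records = list(records)
    if not records:
        raise SequenceError("refusing to write an empty FASTA file")
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description) for r in records
    ]
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            SeqIO.write(seqrecords, fh, "fasta")
    else:
        SeqIO.write(seqrecords, sink, "fasta")


def load_labeled(
    positive: "str | Path | io.TextIOBase",
    negative: "str | Path | io.TextIOBase",
    policy: str = "strict-drop",
) -> LabeledDataset:
    """Load a two-FASTA training set (positives then negatives, file order)."""
    pos = read_fasta(positive, policy)
    neg = read_fasta(negative, policy)
    ids = [s.id for s in pos] + [s.id for s in neg]
    if len(ids) != len(set(ids)):
        raise SequenceError("duplicate ids across positive and negative sets")
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=int)
    return LabeledDataset(sequences=pos + neg, labels=labels)
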