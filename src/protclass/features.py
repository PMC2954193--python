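"""Compositional feature encodings for protein sequences.

Four encodings over the fixed alphabetical residue order A,C,D,...,Y:

- AAC (20-d): fraction of each residue in the sequence.
- SAAC (60-d): AAC computed separately on three contiguous thirds and
  concatenated, so terminal and core composition are kept apart.
- DPC (400-d): fraction of each ordered adjacent residue pair among the
  N-1 adjacent pairs.
- gapped dipeptides (400-d): ordered pairs separated by `gap` intervening
  residues, normalized by the N-gap-1 valid positions; gap=1 is the
  "2-gram" encoding, gap=0 reduces to DPC.

All vectors live on the probability simplex (each normalization block sums
to 1), so no further scaling is applied before classification.

Pair index convention: pair (a, b) maps to 20*index(a) + index(b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import AA_INDEX, ALPHABET, ProteinSequence

ENCODINGS = ("AAC", "SAAC", "DPC", "GAP1", "PSSM400")
ENCODING_DIMS = {"AAC": 20, "SAAC": 60, "DPC": 400, "GAP1": 400, "PSSM400": 400}


class FeatureError(ValueError):
    """Raised for invalid encoder input."""


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-dimension numeric encoding of one sequence."""

    encoding_name: str
    values: np.ndarray
    sequence_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.encoding_name not in ENCODING_DIMS:
            raise FeatureError(f"unknown encoding {self.encoding_name!r}")
        expected = ENCODING_DIMS[self.encoding_name]
        if self.values.shape != (expected,):
            raise FeatureError(
                f"{self.encoding_name} vector must have dimension {expected}, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("feature values must be finite")

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


def _residue_indices(seq: ProteinSequence) -> np.ndarray:
    return np.fromiter((AA_INDEX[a] for a in seq.residues), dtype=int, count=seq.n)


def aac(seq: ProteinSequence) -> FeatureVector:
    """Amino-acid composition: count(residue)/N for each of the 20 residues."""
    idx = _residue_indices(seq)
    counts = np.bincount(idx, minlength=20).astype(float)
    return FeatureVector("AAC", counts / seq.n, seq.id)


def saac_parts(seq: ProteinSequence) -> tuple[str, str, str]:
    """Split into three contiguous parts: floor(N/3), floor(N/3), remainder."""
    if seq.n < 3:
        raise FeatureError(f"sequence {seq.id!r} too short for SAAC (N={seq.n} < 3)")
    k = seq.n // 3
    r = seq.residues
    return r[:k], r[k : 2 * k], r[2 * k :]


def saac(seq: ProteinSequence) -> FeatureVector:
    """Split amino-acid composition: AAC of each third, concatenated (60-d)."""
    blocks = [
        aac(ProteinSequence(id=f"{seq.id}/part{i}", residues=part)).values
        for i, part in enumerate(saac_parts(seq), start=1)
    ]
    return FeatureVector("SAAC", np.concatenate(blocks), seq.id)


def dpc(seq: ProteinSequence) -> FeatureVector:
    """Dipeptide composition: adjacent ordered-pair counts / (N-1)."""
    if seq.n < 2:
        raise FeatureError(f"sequence {seq.id!r} too short for DPC (N={seq.n} < 2)")
    idx = _residue_indices(seq)
    pair_idx = 20 * idx[:-1] + idx[1:]
    counts = np.bincount(pair_idx, minlength=400).astype(float)
    return FeatureVector("DPC", counts / (seq.n - 1), seq.id)


def gapped_dpc(seq: ProteinSequence, gap: int = 1) -> FeatureVector:
    """Gapped dipeptide composition: pairs `gap` residues apart / (N-gap-1).

    gap=1 gives the one-gap "2-gram" encoding; gap=0 is identical to DPC.
    """
    if gap < 0:
        raise FeatureError("gap must be non-negative")
    span = gap + 1
    if seq.n < span + 1:
        raise FeatureError(
            f"sequence {seq.id!r} too short for gap={gap} dipeptides (N={seq.n})"
        )
    idx = _residue_indices(seq)
    pair_idx = 20 * idx[:-span] + idx[span:]
    counts = np.bincount(pair_idx, minlength=400).astype(float)
    name = "DPC" if gap == 0 else "GAP1"
    if gap > 1:
        # same 400-d layout; keep the GAP1 tag only for the canonical gap
        name = "GAP1"
    return FeatureVector(name, counts / (seq.n - span), seq.id)


def feature_names(encoding: str) -> list[str]:
    """Column names for an encoding, e.g. AAC_A or DPC_AC."""
    if encoding == "AAC":
        return [f"AAC_{a}" for a in ALPHABET]
    if encoding == "SAAC":
        return [f"SAAC{part}_{a}" for part in (1, 2, 3) for a in ALPHABET]
    if encoding in ("DPC", "GAP1", "PSSM400"):
        return [f"{encoding}_{a}{b}" for a in ALPHABET for b in ALPHABET]
    raise FeatureError(f"unknown encoding {encoding!r}")


_COMPOSITIONAL = {
    "AAC": aac,
    "SAAC": saac,
    "DPC": dpc,
    "GAP1": gapped_dpc,
}


def encode(seq: ProteinSequence, encoding: str) -> FeatureVector:
    """Encode one sequence with a compositional encoding by name.

    PSSM400 is profile-based and lives in :mod:`protclass.pssm`.
    """
    try:
        fn = _COMPOSITIONAL[encoding]
    except KeyError:
        raise FeatureError(
            f"encoding {encoding!r} is not compositional (choose from {sorted(_COMPOSITIONAL)})"
        ) from None
    return fn(seq)


def encode_matrix(
    sequences: "list[ProteinSequence]", encoding: str
) -> tuple[np.ndarray, list[str]]:
    """Encode many sequences into an (n, dim) matrix plus the id list."""
    vecs = [encode(s, encoding) for s in sequences]
    return np.vstack([v.values for v in vecs]), [s.id for s in sequences]


def to_sparse_lines(X: np.ndarray, labels: np.ndarray) -> list[str]:
    """Render features as sparse classifier-input lines, 1-based indices.

    Format per line: ``<+1|-1> <index>:<value> ...`` with zero entries
    omitted, as consumed by SVMlight-style tools.
    """
    lines = []
    for row, y in zip(np.asarray(X, dtype=float), np.asarray(labels, dtype=int)):
        tag = "+1" if y == 1 else "-1"
        feats = " ".join(f"{j + 1}:{v:g}" for j, v in enumerate(row) if v != 0.0)
        lines.append(f"{tag} {feats}".rstrip())
    return lines


def write_feature_tsv(X: np.ndarray, ids: list[str], encoding: str, sink) -> None:
    """Write a feature matrix as TSV with named columns and an id column."""
    import pandas as pd

    df = pd.DataFrame(np.asarray(X, dtype=float), columns=feature_names(encoding))
    df.insert(0, "sequence_id", ids)
    df.to_csv(sink, sep="\t", index=False)
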