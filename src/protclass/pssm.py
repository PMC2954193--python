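"""PSI-BLAST PSSM profiles: parsing, logistic normalization, and the
400-dimension evolutionary composition encoding.

A position-specific scoring matrix holds one row of 20 integer log-odds
substitution scores per query position (20 x N values for a query of
length N). Scores are squashed to (0, 1) with the logistic function
g(x) = 1 / (1 + exp(-x)), then collapsed to a fixed-length vector: for
each query-residue type a and substitution column b, the normalized
scores g(x)[p][b] are summed over the positions p whose query residue is
a and divided by N. Length-normalizing the sum keeps vectors from
proteins of different lengths comparable, matching the composition
framing of the other encoders; plain sum and per-residue mean are
available behind the ``aggregate`` switch but are not the default.

The parser consumes the standard PSI-BLAST ASCII layout
(``-out_ascii_pssm``): header lines, a 40-letter column-label line, one
line per position with the index, the query residue, 20 log-odds
integers (kept) and 20 percentage columns (ignored). File columns are in
PSI-BLAST residue order A R N D C Q E G H I L K M F P S T W Y V and are
remapped to this package's alphabetical order on input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FeatureVector
from .sequence_io import AA_INDEX, ALPHABET, ProteinSequence

#: Residue column order in PSI-BLAST ASCII PSSM files.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"
_REMAP = np.array([AA_INDEX[a] for a in PSIBLAST_ORDER])  # file col -> alphabetical col

#: Accepted band for log-odds scores; values outside indicate a bad parse.
SCORE_BAND = 20


class PSSMError(ValueError):
    """Raised for malformed profiles or profile/sequence mismatches."""


@dataclass(frozen=True)
class PSSMProfile:
    """Raw integer log-odds profile, columns in alphabetical residue order."""

    sequence_id: str
    query_residues: str
    scores: np.ndarray  # (N, 20) int
    source: str = "synthetic"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=int)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise PSSMError(f"profile matrix must be N x 20, got {scores.shape}")
        if scores.shape[0] != len(self.query_residues):
            raise PSSMError(
                f"profile has {scores.shape[0]} rows but query has "
                f"{len(self.query_residues)} residues"
            )
        if np.abs(scores).max(initial=0) > SCORE_BAND:
            raise PSSMError(f"log-odds score outside +-{SCORE_BAND} band")

    @property
    def n(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class NormalizedProfile:
    """Logistic-normalized profile; every entry strictly in (0, 1)."""

    sequence_id: str
    query_residues: str
    values: np.ndarray  # (N, 20) float in (0,1)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.query_residues), 20):
            raise PSSMError("normalized profile shape mismatch")
        if not (np.all(values > 0.0) and np.all(values < 1.0)):
            raise PSSMError("normalized entries must lie strictly in (0, 1)")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def logistic(x):
    """g(x) = 1 / (1 + exp(-x)); g(0) = 0.5 exactly."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logistic_normalize(profile: PSSMProfile) -> NormalizedProfile:
    """Squash every log-odds score into (0, 1) with the logistic function."""
    return NormalizedProfile(
        sequence_id=profile.sequence_id,
        query_residues=profile.query_residues,
        values=logistic(profile.scores),
        source=profile.source,
    )


def parse_psiblast_pssm(text: str, sequence_id: str | None = None, source: str = "") -> PSSMProfile:
    """Parse PSI-BLAST ASCII PSSM content into a :class:`PSSMProfile`.

    Only the first block of 20 log-odds columns is retained; columns are
    remapped from PSI-BLAST order to alphabetical order. Raises
    :class:`PSSMError` on a missing column-label line, a row without 20
    integer scores (named by line number), or non-consecutive position
    indices.
    """
    lines = text.splitlines()
    label_idx = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 40 and all(t in ALPHABET for t in toks[:40]) and "".join(toks[:20]) == PSIBLAST_ORDER:
            label_idx = i
            break
    if label_idx is None:
        raise PSSMError("not a PSSM file: no PSI-BLAST column-label line found")

    residues: list[str] = []
    rows: list[list[int]] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[label_idx + 1 :], start=label_idx + 2):
        toks = line.split()
        if not toks:
            break
        if not toks[0].lstrip("-").isdigit():
            break  # trailing statistics block
        # a full row is index + residue + 40 score columns (+ trailing
        # weights); a 22-token row (log-odds block only) is also accepted.
        # Anything between betrays a truncated first block, which the
        # percentage zeros would otherwise silently backfill.
        if len(toks) != 22 and len(toks) < 42:
            raise PSSMError(
                f"line {lineno}: expected 20 log-odds scores, row has {len(toks)} fields"
            )
        try:
            pos = int(toks[0])
            residue = toks[1]
            scores = [int(t) for t in toks[2:22]]
        except ValueError as exc:
            raise PSSMError(f"line {lineno}: malformed PSSM row ({exc})") from None
        if pos != expected_pos:
            raise PSSMError(f"line {lineno}: position index {pos}, expected {expected_pos}")
        expected_pos += 1
        residues.append(residue)
        rows.append(scores)
    if not rows:
        raise PSSMError("PSSM file contains no position rows")

    raw = np.array(rows, dtype=int)
    remapped = np.empty_like(raw)
    remapped[:, _REMAP] = raw  # file column j belongs at alphabetical index _REMAP[j]
    return PSSMProfile(
        sequence_id=sequence_id or "query",
        query_residues="".join(residues),
        scores=remapped,
        source=source or "parsed",
    )


def read_pssm_file(path, sequence_id: str | None = None) -> PSSMProfile:
    path = Path(path)
    return parse_psiblast_pssm(path.read_text(), sequence_id=sequence_id, source=str(path))


def write_ascii_pssm(profile: PSSMProfile, sink) -> None:
    """Write a profile in the PSI-BLAST ASCII layout (fixture writer).

    The percentage block is written as zeros; :func:`parse_psiblast_pssm`
    round-trips the log-odds block exactly.
    """
    buf = io.StringIO()
    buf.write("\n")
    buf.write("Last position-specific scoring matrix computed\n")
    header = " ".join(f"{a:>3}" for a in PSIBLAST_ORDER)
    buf.write(f"          {header} {header}\n")
    for p, residue in enumerate(profile.query_residues, start=1):
        row = profile.scores[p - 1][_REMAP]  # back to PSI-BLAST column order
        scores = " ".join(f"{v:>3d}" for v in row)
        zeros = " ".join(f"{0:>3d}" for _ in range(20))
        buf.write(f"{p:>5d} {residue} {scores} {zeros}  0.00 0.00\n")
    buf.write("\n")
    buf.write("                      K         Lambda\n")
    text = buf.getvalue()
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


_AGGREGATES = ("length-normalized-sum", "sum", "mean-per-residue")


def pssm400(
    profile: NormalizedProfile,
    seq: ProteinSequence,
    aggregate: str = "length-normalized-sum",
) -> FeatureVector:
    """Collapse a normalized profile to the 400-d evolutionary composition.

    Output index 20*idx(a)+idx(b) aggregates the normalized scores in
    column b over positions whose query residue is a. Residue types
    absent from the sequence contribute a zero block. The profile's query
    residues must match the sequence; profile rows whose query residue is
    not a canonical amino acid are excluded first, so a profile computed
    before sanitization still aligns.
    """
    if aggregate not in _AGGREGATES:
        raise PSSMError(f"unknown aggregate {aggregate!r} (choose from {_AGGREGATES})")
    residues = profile.query_residues
    values = profile.values
    if residues != seq.residues:
        keep = [i for i, a in enumerate(residues) if a in AA_INDEX]
        residues = "".join(residues[i] for i in keep)
        values = values[keep]
        if residues != seq.residues:
            raise PSSMError(
                f"profile/sequence mismatch for {seq.id!r}: profile query "
                f"{profile.query_residues!r} does not reduce to sequence residues"
            )
    out = np.zeros((20, 20), dtype=float)
    counts = np.zeros(20, dtype=float)
    for pos, a in enumerate(residues):
        i = AA_INDEX[a]
        out[i] += values[pos]
        counts[i] += 1
    if aggregate == "length-normalized-sum":
        out /= len(residues)
    elif aggregate == "mean-per-residue":
        nz = counts > 0
        out[nz] /= counts[nz, None]
    return FeatureVector("PSSM400", out.ravel(), seq.id)


def synthesize_profile(
    seq: ProteinSequence,
    self_score: int = 5,
    off_score: int = -2,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PSSMProfile:
    """Build a deterministic synthetic profile for a sequence.

    At each position the column matching the query residue receives
    ``self_score`` and the rest ``off_score``, plus integer-rounded
    Gaussian noise (standard deviation ``noise_sd``, seeded). Scores are
    clamped to the parser's accepted band. Stands in for PSI-BLAST output
    in tests and simulations.
    """
    if self_score <= off_score:
        raise PSSMError("self_score must exceed off_score")
    rng = np.random.default_rng(seed)
    scores = np.full((seq.n, 20), off_score, dtype=float)
    for pos, a in enumerate(seq.residues):
        scores[pos, AA_INDEX[a]] = self_score
    if noise_sd > 0:
        scores += rng.normal(0.0, noise_sd, size=scores.shape)
    scores = np.clip(np.rint(scores), -SCORE_BAND, SCORE_BAND).astype(int)
    return PSSMProfile(
        sequence_id=seq.id, query_residues=seq.residues, scores=scores, source="synthetic"
    )


def encode_pssm400(
    seq: ProteinSequence, profile: PSSMProfile, aggregate: str = "length-normalized-sum"
) -> FeatureVector:
    """Convenience: raw profile -> logistic normalization -> 400-d vector."""
    return pssm400(logistic_normalize(profile), seq, aggregate=aggregate)
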