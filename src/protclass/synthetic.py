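"""Synthetic labeled datasets with a planted composition signal.

Two sequence classes are drawn i.i.d. from residue-composition
distributions that share a common background (average protein residue
frequencies) but differ by a controllable effect: the positive class
up-weights the residues {E, K, P, R} by a factor (1 + effect * k) with
gain k = 1.5, then renormalizes. At effect = 0 the classes are
identical (null model); at effect = 1 the up-weighted residues are
enriched 2.5-fold before renormalization, a strong, easily learnable
signal. Because the signal is compositional, every encoder in the
package (AAC, SAAC, DPC, gapped dipeptides, PSSM-400 via synthetic
profiles) is sensitive to it.

Everything is a pure function of the spec: the same spec yields
byte-identical FASTA output and identical profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pssm as pssm_mod
from .sequence_io import ALPHABET, LabeledDataset, ProteinSequence

#: Background residue frequencies (alphabetical order A..Y), rounded
#: average composition of well-curated protein databases.
BACKGROUND = {
    "A": 0.0826, "C": 0.0136, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0394, "R": 0.0553,
    "S": 0.0661, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}

#: Residues enriched in the positive class (frozen so tests are stable).
UPWEIGHTED = ("E", "K", "P", "R")

#: Gain factor: positive-class weight = background * (1 + effect * GAIN).
GAIN = 1.5


class SyntheticError(ValueError):
    """Raised for an invalid synthetic-data specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic dataset draw."""

    n_pos: int = 56
    n_neg: int = 300
    length_range: tuple[int, int] = (50, 300)
    effect: float = 0.9
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise SyntheticError("class sizes must be positive")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise SyntheticError("length_range must satisfy 3 <= min <= max")
        if not 0.0 <= self.effect <= 1.0:
            raise SyntheticError("effect must lie in [0, 1]")


def class_compositions(effect: float) -> tuple[np.ndarray, np.ndarray]:
    """(positive, negative) residue distributions in alphabetical order."""
    base = np.array([BACKGROUND[a] for a in ALPHABET])
    base = base / base.sum()
    pos = base.copy()
    for a in UPWEIGHTED:
        pos[ALPHABET.index(a)] *= 1.0 + effect * GAIN
    pos /= pos.sum()
    return pos, base


def _draw_sequences(
    rng: np.random.Generator,
    n: int,
    comp: np.ndarray,
    length_range: tuple[int, int],
    prefix: str,
) -> list[ProteinSequence]:
    lo, hi = length_range
    width = len(str(n))
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(list(ALPHABET), size=length, p=comp))
        out.append(ProteinSequence(id=f"{prefix}_{i + 1:0{width}d}", residues=residues))
    return out


def generate(spec: SyntheticSpec = SyntheticSpec()) -> LabeledDataset:
    """Draw a labeled dataset (positives first, then negatives)."""
    rng = np.random.default_rng(spec.seed)
    pos_comp, neg_comp = class_compositions(spec.effect)
    pos = _draw_sequences(rng, spec.n_pos, pos_comp, spec.length_range, "pos")
    neg = _draw_sequences(rng, spec.n_neg, neg_comp, spec.length_range, "neg")
    labels = np.array([1] * spec.n_pos + [0] * spec.n_neg, dtype=int)
    return LabeledDataset(sequences=pos + neg, labels=labels)


def generate_with_profiles(
    spec: SyntheticSpec = SyntheticSpec(),
    self_score: int = 5,
    off_score: int = -2,
    noise_sd: float = 1.0,
) -> tuple[LabeledDataset, list[pssm_mod.PSSMProfile]]:
    """Dataset plus one matched synthetic PSSM profile per sequence.

    Per-sequence profile seeds are spawned deterministically from the
    spec seed, so profiles inherit full reproducibility.
    """
    dataset = generate(spec)
    seed_seq = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(dataset))]
    profiles = [
        pssm_mod.synthesize_profile(
            seq, self_score=self_score, off_score=off_score, noise_sd=noise_sd, seed=child
        )
        for seq, child in zip(dataset.sequences, child_seeds)
    ]
    return dataset, profiles
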