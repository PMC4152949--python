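"""Synthetic two-class DNA sequence generator.

Real DHS sequences are enriched in the G+C dinucleotides CC, CG, GC and GG
relative to non-DHS background.  The generator reproduces that contrast with
first-order Markov chains: the negative class draws every base uniformly,
while the positive class adds a log-odds boost ``delta`` to every transition
*into* C or G before renormalizing each row.  First-order chains (rather
than i.i.d. bases) make the dinucleotide frequencies — the discriminative
signal — directly controllable.

``delta = 0`` makes the two classes identically distributed (the null
configuration); increasing ``delta`` strengthens the class contrast.
Sequence lengths are drawn uniformly from a configurable range (default
200-400 bp, a plausible regulatory-element scale).

Seed discipline: one master seed is expanded with ``numpy.random.SeedSequence``
into an independent stream per sequence, so generating a longer dataset
leaves the sequences shared with a shorter one byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DhspredError
from .io import NEGATIVE, POSITIVE, LabeledDataset, NucleotideSequence

BASES = "ACGT"
_INTO_CG = np.array([0.0, 1.0, 1.0, 0.0])  # columns C and G


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_pos: int
    n_neg: int
    length_min: int = 200
    length_max: int = 400
    delta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise DhspredError("sequence counts must be non-negative")
        if not 2 <= self.length_min <= self.length_max:
            raise DhspredError(
                f"need 2 <= length_min <= length_max, got "
                f"[{self.length_min}, {self.length_max}]"
            )
        if self.delta < 0:
            raise DhspredError(f"delta must be >= 0, got {self.delta}")


def uniform_matrix() -> np.ndarray:
    """The background transition matrix: every base equally likely."""
    return np.full((4, 4), 0.25)


def cg_biased_matrix(delta: float) -> np.ndarray:
    """Uniform matrix with log-odds ``delta`` added to transitions into C/G."""
    logits = np.log(uniform_matrix()) + delta * _INTO_CG[None, :]
    m = np.exp(logits)
    return m / m.sum(axis=1, keepdims=True)


def generate_sequence(
    length: int, transition: np.ndarray, rng: np.random.Generator, seq_id: str = "seq"
) -> NucleotideSequence:
    """Sample one sequence from a first-order Markov chain.

    The first base is uniform over A/C/G/T; each following base is drawn
    from the row of its predecessor.
    """
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (4, 4) or np.any(transition < 0):
        raise DhspredError("transition matrix must be 4x4 with non-negative entries")
    if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-9):
        raise DhspredError("transition matrix rows must each sum to 1")
    if length < 2:
        raise DhspredError(f"length must be >= 2, got {length}")
    # cumulative rows let the whole chain run on one uniform draw per base
    cum = np.cumsum(transition, axis=1)
    u = rng.random(length)
    states = np.empty(length, dtype=np.intp)
    states[0] = min(int(u[0] * 4), 3)
    for i in range(1, length):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i], side="right")
    residues = "".join(BASES[s] for s in states)
    return NucleotideSequence(id=seq_id, residues=residues)


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Generate the two-class dataset described by ``config``.

    Positives use the delta-boosted matrix, negatives the uniform one;
    output order is positives first, then negatives.
    """
    pos_matrix = cg_biased_matrix(config.delta)
    neg_matrix = uniform_matrix()
    # one stream per class, then one per sequence: growing either class
    # leaves every already-generated sequence byte-identical
    pos_stream, neg_stream = np.random.SeedSequence(config.seed).spawn(2)
    sequences: list[NucleotideSequence] = []
    labels: list[str] = []
    for prefix, matrix, label, stream, n in (
        ("pos", pos_matrix, POSITIVE, pos_stream, config.n_pos),
        ("neg", neg_matrix, NEGATIVE, neg_stream, config.n_neg),
    ):
        for i, child in enumerate(stream.spawn(n)):
            rng = np.random.default_rng(child)
            length = int(rng.integers(config.length_min, config.length_max + 1))
            sequences.append(
                generate_sequence(length, matrix, rng, seq_id=f"{prefix}_{i + 1:04d}")
            )
            labels.append(label)
    return LabeledDataset(
        sequences=tuple(sequences),
        labels=tuple(labels),
        name=f"synthetic(delta={config.delta},seed={config.seed})",
    )
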