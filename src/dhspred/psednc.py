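"""Pseudo dinucleotide composition (PseDNC) encoding.

A DNA sequence of length L is mapped to a (16 + lambda)-dimensional
descriptor D combining local composition and global sequence order:

* components 1..16 — the normalized frequencies f_u of the 16 overlapping
  dinucleotides (lexicographic order AA..TT);
* components 17..16+lambda — lambda tier correlation factors theta_j, each
  the average structural dissimilarity Theta between dinucleotides j
  positions apart, down-weighted by a factor w in [0, 1]:

    d_u = f_u / (1 + w * sum_j theta_j)            for u <= 16
    d_u = w * theta_{u-16} / (1 + w * sum_j theta_j)  otherwise

  (the denominator uses sum_i f_i = 1).  The vector is therefore
  non-negative and sums to one.  Theta is the mean squared difference of the
  standardized structural-property values of the two dinucleotides (see
  :mod:`dhspred.properties`).

At w = 0 the descriptor degenerates to the plain dinucleotide composition;
larger lambda injects longer-range order information at the price of
dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DhspredError, EncodingError, SequenceTooShortError
from .io import NEGATIVE, POSITIVE, LabeledDataset, NucleotideSequence
from .properties import DINUCLEOTIDES, PropertyTable

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PseDNCVector:
    """The descriptor D for one sequence, with its ingredients kept visible."""

    components: np.ndarray  # length 16 + lam
    f: np.ndarray  # 16 dinucleotide frequencies
    theta: np.ndarray  # lam tier correlation factors
    w: float
    lam: int

    @property
    def dimension(self) -> int:
        return 16 + self.lam


def _dinucleotide_codes(seq: NucleotideSequence) -> np.ndarray:
    """Integer code 4*first+second for each of the L-1 overlapping steps."""
    base = np.fromiter((_BASE_CODE[b] for b in seq.residues), dtype=np.intp)
    return base[:-1] * 4 + base[1:]


def dinucleotide_frequencies(seq: NucleotideSequence) -> np.ndarray:
    """Normalized occurrence frequencies of the 16 overlapping dinucleotides.

    Counts the L-1 steps R_i R_{i+1} and divides by L-1; the result sums
    to one.  Order is lexicographic AA, AC, ..., TT.
    """
    codes = _dinucleotide_codes(seq)
    counts = np.bincount(codes, minlength=16).astype(float)
    return counts / codes.size


def theta_pair(x: str, y: str, table: PropertyTable) -> float:
    """Structural correlation distance Theta between two dinucleotides.

    Mean squared difference of the standardized property values; symmetric,
    zero on the diagonal.
    """
    for d in (x, y):
        if d not in DINUCLEOTIDES:
            raise DhspredError(f"unknown dinucleotide {d!r}")
    m = table.theta_matrix()
    return float(m[DINUCLEOTIDES.index(x), DINUCLEOTIDES.index(y)])


def tier_correlations(
    seq: NucleotideSequence,
    lam: int,
    table: PropertyTable,
    theta_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """The lambda tier correlation factors theta_1..theta_lambda.

    ``theta_j`` averages ``Theta(R_i R_{i+1}, R_{i+j} R_{i+j+1})`` over all
    ``i = 1..L-1-j``; the sequence must satisfy ``L >= lambda + 2`` so the
    deepest tier has at least one summand.

    ``theta_matrix`` may be passed to reuse a precomputed 16x16 Theta matrix
    across many sequences.
    """
    if lam < 1:
        raise DhspredError(f"lambda must be >= 1, got {lam}")
    L = len(seq)
    if L < lam + 2:
        raise SequenceTooShortError(
            f"sequence {seq.id!r}: length {L} < lambda + 2 = {lam + 2}"
        )
    if theta_matrix is None:
        theta_matrix = table.theta_matrix()
    codes = _dinucleotide_codes(seq)
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        theta[j - 1] = theta_matrix[codes[:-j], codes[j:]].mean()
    return theta


def psednc_encode(
    seq: NucleotideSequence,
    w: float,
    lam: int,
    table: PropertyTable,
    theta_matrix: np.ndarray | None = None,
) -> PseDNCVector:
    """Encode one sequence as a (16 + lambda)-dimensional PseDNC vector."""
    if not 0.0 <= w <= 1.0:
        raise DhspredError(f"weight w must lie in [0, 1], got {w}")
    f = dinucleotide_frequencies(seq)
    theta = tier_correlations(seq, lam, table, theta_matrix=theta_matrix)
    denom = 1.0 + w * theta.sum()  # sum of f is exactly 1
    components = np.concatenate([f, w * theta]) / denom
    return PseDNCVector(components=components, f=f, theta=theta, w=float(w), lam=int(lam))


def encode_dataset(
    data: LabeledDataset,
    w: float,
    lam: int,
    table: PropertyTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every sequence; returns (n x (16+lambda) matrix, +/-1 labels).

    Row order follows dataset order; labels map positive -> +1,
    negative -> -1 (0 for unlabeled rows).  Sequences too short for the
    requested lambda are collected into one aggregate
    :class:`~dhspred.exceptions.EncodingError` naming the offending ids.
    """
    theta_matrix = table.theta_matrix()
    rows: list[np.ndarray] = []
    failed: list[str] = []
    for seq, _ in data:
        try:
            rows.append(
                psednc_encode(seq, w, lam, table, theta_matrix=theta_matrix).components
            )
        except SequenceTooShortError:
            failed.append(seq.id)
    if failed:
        raise EncodingError(
            f"{len(failed)} sequence(s) shorter than lambda + 2 = {lam + 2}: "
            + ", ".join(failed[:10])
            + ("..." if len(failed) > 10 else ""),
            failed_ids=failed,
        )
    X = np.vstack(rows) if rows else np.empty((0, 16 + lam))
    y = np.array(
        [1 if lab == POSITIVE else -1 if lab == NEGATIVE else 0 for _, lab in data],
        dtype=int,
    )
    return X, y


def write_feature_tsv(path, data: LabeledDataset, X: np.ndarray) -> None:
    """Feature matrix as TSV: ``id  label  d1..d{16+lambda}``."""
    with open(path, "w") as fh:
        header = ["id", "label"] + [f"d{i + 1}" for i in range(X.shape[1])]
        fh.write("\t".join(header) + "\n")
        for (seq, lab), row in zip(data, X):
            fh.write(
                "\t".join([seq.id, lab if lab else "unlabeled"] + [f"{v:.12g}" for v in row])
                + "\n"
            )


def write_libsvm(path, X: np.ndarray, y: np.ndarray) -> None:
    """Sparse text format ``label index:value ...`` with 1-based indices."""
    from sklearn.datasets import dump_svmlight_file

    dump_svmlight_file(X, y, str(path), zero_based=False)
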