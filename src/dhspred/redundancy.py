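"""Greedy redundancy filtering of sequence sets at a pairwise-identity cutoff.

Mirrors the clustering contract of greedy incremental tools such as CD-HIT:
sequences are visited longest-first, each either joins the first retained
representative it matches at or above the identity threshold or founds a new
cluster.  Identity between two sequences is defined as the number of matched
bases in the gapless-cost-free global alignment that maximizes matches
(equivalently, the length of the longest common subsequence) divided by the
length of the shorter sequence — the convention of CD-HIT's identity ratio.

The two classes of a labeled dataset are clustered independently by default,
so a positive is never discarded for resembling a negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DhspredError
from .io import LabeledDataset, NucleotideSequence


def _lcs_length(a: str, b: str) -> int:
    """Longest-common-subsequence length, row-wise DP vectorized with numpy."""
    if not a or not b:
        return 0
    bx = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(bx.size + 1, dtype=np.int32)
    for ch in a.encode():
        match = prev[:-1] + (bx == ch)
        cur = np.empty_like(prev)
        cur[0] = 0
        # cur[j] = max(prev[j], match[j-1], cur[j-1]); the cur[j-1] dependence
        # is a running maximum, resolved with maximum.accumulate
        np.maximum(prev[1:], match, out=cur[1:])
        np.maximum.accumulate(cur, out=cur)
        prev = cur
    return int(prev[-1])


def pairwise_identity(a: NucleotideSequence, b: NucleotideSequence) -> float:
    """Fraction of the shorter sequence matched in the max-match alignment.

    Symmetric, 1.0 for identical sequences, 0.0 when no common subsequence
    exists (impossible only if the two share no base at all).
    """
    return _lcs_length(a.residues, b.residues) / min(len(a), len(b))


@dataclass(frozen=True)
class ClusterResult:
    """Representatives plus the member -> representative mapping."""

    representatives: LabeledDataset
    cluster_map: dict[str, str]
    threshold: float


def _greedy_cluster(indices: list[int], data: LabeledDataset, threshold: float):
    """Greedy longest-first clustering within one class; returns (kept, map)."""
    # stable sort: length descending, ties by input order
    order = sorted(indices, key=lambda i: -len(data.sequences[i]))
    reps: list[int] = []
    mapping: dict[str, str] = {}
    for i in order:
        seq = data.sequences[i]
        for r in reps:
            if pairwise_identity(seq, data.sequences[r]) >= threshold:
                mapping[seq.id] = data.sequences[r].id
                break
        else:
            reps.append(i)
            mapping[seq.id] = seq.id
    return reps, mapping


def filter_redundant(
    data: LabeledDataset,
    threshold: float,
    cross_class: bool = False,
) -> ClusterResult:
    """Reduce ``data`` so no two retained sequences reach ``threshold`` identity.

    Parameters
    ----------
    data
        Labeled (or unlabeled) dataset; an empty dataset yields an empty result.
    threshold
        Identity fraction in (0, 1]; a pair at or above it is redundant.
    cross_class
        If True the whole dataset is clustered jointly; by default each label
        class is clustered separately.

    Representatives are returned in original dataset order.
    """
    if not 0.0 < threshold <= 1.0:
        raise DhspredError(f"threshold must lie in (0, 1], got {threshold}")
    if cross_class:
        groups = [list(range(len(data)))]
    else:
        by_label: dict[object, list[int]] = {}
        for i, (_, lab) in enumerate(data):
            by_label.setdefault(lab, []).append(i)
        groups = list(by_label.values())
    kept: set[int] = set()
    mapping: dict[str, str] = {}
    for indices in groups:
        reps, m = _greedy_cluster(indices, data, threshold)
        kept.update(reps)
        mapping.update(m)
    rep_indices = sorted(kept)
    return ClusterResult(
        representatives=data.subset(rep_indices),
        cluster_map=mapping,
        threshold=threshold,
    )


def write_cluster_map(path, result: ClusterResult) -> None:
    """Two-column TSV ``member_id<TAB>representative_id``."""
    with open(path, "w") as fh:
        fh.write("member_id\trepresentative_id\n")
        for member, rep in result.cluster_map.items():
            fh.write(f"{member}\t{rep}\n")
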