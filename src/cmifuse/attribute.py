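"""Sequence-derived attribute features.

circRNAs, whose lengths vary from hundreds to thousands of nucleotides,
are described by a Jaccard profile: each circRNA is reduced to its set of
distinct k-mers (moving window of size 5, stride 1 by default) and its
feature vector is the Jaccard similarity of that set against every circRNA
in the corpus, giving a corpus-length vector in [0,1] with a unit
self-entry.  miRNAs (~20-22 nt) are embedded by a small masked-language-
model transformer (see :mod:`cmifuse.embedder`).  A pair's attribute view
is the concatenation of the circRNA profile and the miRNA embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import SequenceRecord


@dataclass(frozen=True)
class KmerSet:
    """Distinct fixed-length substrings of one sequence (set semantics)."""

    k: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if any(len(m) != self.k for m in self.members):
            raise ValueError("all members must have length k")


def kmer_set(seq: str, k: int = 5, stride: int = 1, circular: bool = False) -> KmerSet:
    """Distinct k-mers of a sequence under a moving window.

    Windows are linear by default; ``circular=True`` wraps windows across
    the sequence end (circRNAs are covalently closed, so wrapping is a
    defensible alternative exposed for sensitivity analysis).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} shorter than window k={k}")
    if circular:
        extended = seq + seq[: k - 1]
        members = {extended[i : i + k] for i in range(0, len(seq), stride)}
    else:
        members = {seq[i : i + k] for i in range(0, len(seq) - k + 1, stride)}
    return KmerSet(k=k, members=frozenset(members))


def jaccard(a: KmerSet, b: KmerSet) -> float:
    """Jaccard similarity |a n b| / |a u b| of two k-mer sets."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    if not a.members or not b.members:
        raise ValueError("Jaccard undefined for an empty k-mer set")
    inter = len(a.members & b.members)
    union = len(a.members | b.members)
    return inter / union


@dataclass
class AttributeMatrix:
    """Per-node attribute vectors with a fixed ordering of ids."""

    ids: list[str]
    vectors: np.ndarray  # shape (n_ids, dim)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be (n_ids, dim)")
        self._index = {i: row for row, i in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[node_id]]
        except KeyError:
            raise KeyError(f"unknown id {node_id!r}") from None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            for i, row in zip(self.ids, self.vectors):
                out.write(i + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AttributeMatrix":
        ids, rows = [], []
        with open(path) as handle:
            for line in handle:
                fields = line.rstrip("\n").split("\t")
                ids.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(ids=ids, vectors=np.array(rows, dtype=float))


def circ_attribute_matrix(
    records: Sequence[SequenceRecord],
    k: int = 5,
    stride: int = 1,
    circular: bool = False,
) -> AttributeMatrix:
    """All-against-all Jaccard profile matrix over a circRNA corpus.

    Row a holds jaccard(a, e) for every corpus member e in corpus order,
    so the matrix is symmetric with a unit diagonal.
    """
    if not records:
        raise ValueError("empty circRNA corpus")
    sets = [kmer_set(r.seq, k=k, stride=stride, circular=circular) for r in records]
    n = len(sets)
    mat = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard(sets[i], sets[j])
    return AttributeMatrix(ids=[r.id for r in records], vectors=mat)


def pair_attribute_view(
    circ_attr: AttributeMatrix,
    mirna_attr: AttributeMatrix,
    pair: tuple[str, str],
) -> np.ndarray:
    """Attribute view of one pair: [circ profile || miRNA embedding]."""
    c, m = pair
    return np.concatenate([circ_attr.vector(c), mirna_attr.vector(m)])
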