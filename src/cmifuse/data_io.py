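"""Sequence and interaction-pair input, negative sampling, and CV folds.

circRNA-miRNA interaction prediction starts from two flat inputs: FASTA
sequences for each molecule class and a two-column table of known
interacting pairs.  This module reads both, assembles a labeled dataset by
sampling unknown pairs as negatives, and produces stratified
cross-validation folds.  Sequences are normalized to the RNA alphabet
(T -> U) at load time so DNA-style circRNA exports and RNA-style miRNA
exports unify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

MoleculeKind = Literal["circRNA", "miRNA"]

RNA_ALPHABET = frozenset("ACGU")


class FastaFormatError(ValueError):
    """Malformed FASTA input."""


class PairFormatError(ValueError):
    """Malformed interaction-pair table."""


class ReferenceError_(KeyError):
    """A pair references an id absent from the sequence universe."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence of a given molecule kind."""

    id: str
    kind: MoleculeKind
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside "
                f"{{A,C,G,U}} after normalization: {sorted(bad)}"
            )


def normalize_sequence(raw: str) -> str:
    """Uppercase and map T to U (RNA alphabet)."""
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path, kind: MoleculeKind) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    The header token before the first whitespace becomes the id; T is
    normalized to U; entry order is preserved.  Duplicate ids and empty
    sequences raise.
    """
    path = Path(path)
    with open(path) as handle:
        # SeqIO silently yields nothing for a file that does not start
        # with a header line; detect that case with a line number.
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>'"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        seq = normalize_sequence(str(entry.seq))
        if not seq:
            raise FastaFormatError(f"{path}: sequence {entry.id!r} is empty")
        records.append(SequenceRecord(id=entry.id, kind=kind, seq=seq))
    return records


@dataclass
class InteractionSet:
    """Known circRNA-miRNA pairs over an ordered id universe.

    ``circ_index`` / ``mirna_index`` are 0-based, contiguous,
    insertion-ordered maps covering the full id universe (including ids
    with no known pair).
    """

    pairs: list[tuple[str, str]]
    circ_index: dict[str, int]
    mirna_index: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in InteractionSet")
        for c, m in self.pairs:
            if c not in self.circ_index:
                raise ReferenceError_(f"unknown circRNA id {c!r}")
            if m not in self.mirna_index:
                raise ReferenceError_(f"unknown miRNA id {m!r}")

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    @property
    def n_circ(self) -> int:
        return len(self.circ_index)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_index)


def _ordered_index(ids: Iterable[str]) -> dict[str, int]:
    index: dict[str, int] = {}
    for i in ids:
        if i in index:
            raise ValueError(f"duplicate id {i!r}")
        index[i] = len(index)
    return index


def read_interactions(
    path: str | Path,
    circ_ids: Sequence[str],
    mirna_ids: Sequence[str],
) -> InteractionSet:
    """Read a two-column (circ_id, mirna_id) table as an InteractionSet.

    Tab or comma delimiter is sniffed from the first data line; lines
    starting with '#' are skipped.  Duplicate pairs are dropped with a
    logged warning; pairs referencing unknown ids raise.
    """
    path = Path(path)
    circ_index = _ordered_index(circ_ids)
    mirna_index = _ordered_index(mirna_ids)

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    delim: str | None = None
    unknown: list[str] = []
    n_dupes = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if delim is None:
                delim = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(delim)]
            if len(fields) != 2:
                raise PairFormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            c, m = fields
            if c not in circ_index:
                unknown.append(c)
                continue
            if m not in mirna_index:
                unknown.append(m)
                continue
            if (c, m) in seen:
                n_dupes += 1
                continue
            seen.add((c, m))
            pairs.append((c, m))
    if unknown:
        raise ReferenceError_(
            f"{path}: pairs reference ids absent from the sequence sets: "
            f"{sorted(set(unknown))}"
        )
    if n_dupes:
        logger.warning("%s: dropped %d duplicate pair(s)", path, n_dupes)
    return InteractionSet(pairs=pairs, circ_index=circ_index, mirna_index=mirna_index)


def candidate_pool_size(n_circ: int, n_mirna: int, n_positive: int) -> int:
    """Number of unknown (candidate negative) pairs in the bipartite grid.

    Exact integer arithmetic: n_circ * n_mirna - n_positive.
    """
    total = n_circ * n_mirna
    if n_positive > total:
        raise ValueError(
            f"n_positive={n_positive} exceeds grid size {n_circ}x{n_mirna}={total}"
        )
    return total - n_positive


@dataclass
class LabeledPairSet:
    """Positive pairs plus sampled negative pairs with binary labels."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray  # int array of {0,1}
    provenance: list[Literal["known_positive", "sampled_negative"]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("a pair appears twice in LabeledPairSet")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def sample_negatives(
    interactions: InteractionSet,
    ratio: float = 1.0,
    seed: int = 0,
    n_negatives: int | None = None,
) -> LabeledPairSet:
    """All known positives plus uniformly sampled unknown pairs as negatives.

    Negatives are drawn without replacement from the pool of pairs absent
    from ``interactions``; sampling is deterministic for a fixed seed.
    """
    n_pos = len(interactions.pairs)
    if n_negatives is None:
        n_negatives = int(round(ratio * n_pos))
    pool = candidate_pool_size(interactions.n_circ, interactions.n_mirna, n_pos)
    if n_negatives > pool:
        raise ValueError(
            f"requested {n_negatives} negatives but the unknown-pair pool "
            f"has only {pool}"
        )
    rng = np.random.default_rng(seed)
    circ_ids = list(interactions.circ_index)
    mirna_ids = list(interactions.mirna_index)
    positives = interactions.pair_set

    chosen: list[tuple[str, str]] = []
    chosen_set: set[tuple[str, str]] = set()
    if n_negatives > pool // 2:
        # Dense regime: enumerate the pool and choose without replacement.
        all_unknown = [
            (c, m)
            for c in circ_ids
            for m in mirna_ids
            if (c, m) not in positives
        ]
        idx = rng.choice(len(all_unknown), size=n_negatives, replace=False)
        chosen = [all_unknown[i] for i in sorted(idx)]
    else:
        # Sparse regime: rejection sampling against the positive hash set.
        while len(chosen) < n_negatives:
            c = circ_ids[int(rng.integers(interactions.n_circ))]
            m = mirna_ids[int(rng.integers(interactions.n_mirna))]
            if (c, m) in positives or (c, m) in chosen_set:
                continue
            chosen_set.add((c, m))
            chosen.append((c, m))

    pairs = list(interactions.pairs) + chosen
    labels = np.array([1] * n_pos + [0] * n_negatives, dtype=int)
    provenance = ["known_positive"] * n_pos + ["sampled_negative"] * n_negatives
    return LabeledPairSet(pairs=pairs, labels=labels, provenance=provenance)


@dataclass
class FoldSplit:
    """Assignment of each labeled pair to one of k folds."""

    k: int
    assignments: np.ndarray  # int array, pair index -> fold in [0, k)

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.min() < 0 or self.assignments.max() >= self.k:
            raise ValueError("fold assignments out of range")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("pair_index\tfold\n")
            for i, f in enumerate(self.assignments):
                out.write(f"{i}\t{f}\n")


def split_folds(dataset: LabeledPairSet, k: int, seed: int = 0) -> FoldSplit:
    """Stratified k-fold partition of a labeled pair set.

    Each class is shuffled independently and dealt round-robin across
    folds, so per-fold class fractions stay within rounding of the global
    fraction.  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(dataset.pairs), dtype=int)
    for label in (0, 1):
        idx = np.flatnonzero(dataset.labels == label)
        if len(idx) < k:
            raise ValueError(
                f"class {label} has only {len(idx)} samples; cannot make {k} folds"
            )
        rng.shuffle(idx)
        assignments[idx] = np.arange(len(idx)) % k
    return FoldSplit(k=k, assignments=assignments)
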