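"""Sequence and interaction-network I/O.

An lncRNA-protein interaction (LPI) network over ``n`` lncRNAs and ``m``
proteins is a binary matrix ``Y`` with ``Y[i, j] = 1`` when lncRNA ``i`` is
known to interact with protein ``j`` and ``0`` when the pair's status is
unknown.  A 0 is *not* a verified non-interaction: negatives are sampled from
the zero entries downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino-acid"

_NT_ALPHABET = frozenset("ACGT")
# 20 standard one-letter codes in alphabetical order
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_ALPHABET = frozenset(AA_ORDER)
#: code appended for non-standard residues when unknown mapping is enabled
UNKNOWN_AA_CODE = 20


class ParseError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised when data violates a domain invariant."""


def canonicalize(sequence: str, alphabet: str, *, allow_unknown: bool = False) -> str:
    """Upper-case a raw sequence and validate it against its alphabet.

    Nucleotide sequences have U mapped to T (RNA is stored DNA-style so that
    k-mer indexing is uniform).  Amino-acid sequences must use the 20 standard
    one-letter codes; with ``allow_unknown`` any other letter is replaced by
    ``'X'``, which downstream hashing maps to a dedicated code.
    """
    seq = sequence.upper()
    if alphabet == NUCLEOTIDE:
        seq = seq.replace("U", "T")
        bad = set(seq) - _NT_ALPHABET
        if bad:
            raise ValidationError(
                f"non-ACGT character(s) {sorted(bad)} in nucleotide sequence"
            )
        return seq
    if alphabet == AMINO_ACID:
        bad = set(seq) - _AA_ALPHABET
        if bad:
            if not allow_unknown:
                raise ValidationError(
                    f"non-standard amino-acid character(s) {sorted(bad)}"
                )
            seq = "".join(c if c in _AA_ALPHABET else "X" for c in seq)
        return seq
    raise ValueError(f"unknown alphabet {alphabet!r}")


@dataclass(frozen=True)
class SequenceRecord:
    """One identified biological sequence with a declared alphabet."""

    id: str
    sequence: str
    alphabet: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        if self.alphabet not in (NUCLEOTIDE, AMINO_ACID):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(
    path: str | Path, alphabet: str, *, allow_unknown: bool = False
) -> list[SequenceRecord]:
    """Read a FASTA file into canonicalized :class:`SequenceRecord` objects.

    Multi-line bodies are concatenated; sequences are canonicalized per
    ``alphabet`` (see :func:`canonicalize`).  An empty file yields an empty
    list; a record with an empty body or an out-of-alphabet character raises
    an error naming the record.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty header")
        body = str(rec.seq)
        if not body:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence body")
        try:
            seq = canonicalize(body, alphabet, allow_unknown=allow_unknown)
        except ValidationError as exc:
            raise ValidationError(f"record {rec.id!r}: {exc}") from exc
        records.append(SequenceRecord(rec.id, seq, alphabet))
    return records


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a TSV edge list of (lncrna_id, protein_id) pairs.

    Lines starting with ``#`` are treated as comments/headers.  An optional
    third column is tolerated (pre-labeled pairs).  Duplicate pairs are
    collapsed with a logged warning; order of first occurrence is kept.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            pair = (fields[0], fields[1])
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            pairs.append(pair)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return pairs


@dataclass
class InteractionMatrix:
    """Binary lncRNA x protein interaction matrix with identifier indices."""

    lncrna_ids: list[str]
    protein_ids: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int8)
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValidationError("duplicate lncRNA ids")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError("duplicate protein ids")
        if self.Y.shape != (len(self.lncrna_ids), len(self.protein_ids)):
            raise ValidationError(
                f"matrix shape {self.Y.shape} does not match id lists "
                f"({len(self.lncrna_ids)}, {len(self.protein_ids)})"
            )
        if not np.isin(self.Y, (0, 1)).all():
            raise ValidationError("matrix entries must be 0 or 1")
        self._row_index = {lid: i for i, lid in enumerate(self.lncrna_ids)}
        self._col_index = {pid: j for j, pid in enumerate(self.protein_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape

    def row_of(self, lncrna_id: str) -> int:
        return self._row_index[lncrna_id]

    def col_of(self, protein_id: str) -> int:
        return self._col_index[protein_id]

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Row/column indices of all known interactions, row-major order."""
        rows, cols = np.nonzero(self.Y)
        return list(zip(rows.tolist(), cols.tolist()))

    def positive_edges(self) -> list[tuple[str, str]]:
        """Known interactions as (lncrna_id, protein_id) pairs."""
        return [
            (self.lncrna_ids[i], self.protein_ids[j])
            for i, j in self.positive_pairs()
        ]


def build_interaction_matrix(
    lncrnas: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord],
    edges: Iterable[tuple[str, str]],
) -> InteractionMatrix:
    """Build Y from sequence records and an edge list.

    Row/column order follows the record order; every edge id must match a
    record, otherwise a :class:`ValidationError` names the offending id.
    """
    lncrna_ids = [r.id for r in lncrnas]
    protein_ids = [r.id for r in proteins]
    row = {lid: i for i, lid in enumerate(lncrna_ids)}
    col = {pid: j for j, pid in enumerate(protein_ids)}
    Y = np.zeros((len(lncrna_ids), len(protein_ids)), dtype=np.int8)
    for lid, pid in edges:
        if lid not in row:
            raise ValidationError(f"edge references unknown lncRNA id {lid!r}")
        if pid not in col:
            raise ValidationError(f"edge references unknown protein id {pid!r}")
        Y[row[lid], col[pid]] = 1
    return InteractionMatrix(lncrna_ids, protein_ids, Y)


def count_unknown_pairs(matrix: InteractionMatrix) -> int:
    """Number of zero entries of Y: candidate pairs with unknown status."""
    n, m = matrix.shape
    return int(n * m - matrix.Y.sum())


@dataclass
class Dataset:
    """Sequences plus their interaction matrix, with id consistency checked."""

    lncrnas: list[SequenceRecord]
    proteins: list[SequenceRecord]
    interactions: InteractionMatrix

    def __post_init__(self) -> None:
        if [r.id for r in self.lncrnas] != self.interactions.lncrna_ids:
            raise ValidationError("lncRNA records do not match matrix rows")
        if [r.id for r in self.proteins] != self.interactions.protein_ids:
            raise ValidationError("protein records do not match matrix columns")


def write_predictions(
    path: str | Path, ranked: Sequence[tuple[str, str, float, int]]
) -> None:
    """Write a ranked prediction list as TSV: lncrna_id, protein_id, score, rank."""
    with open(path, "w") as handle:
        handle.write("lncrna_id\tprotein_id\tscore\trank\n")
        for lid, pid, score, rank in ranked:
            handle.write(f"{lid}\t{pid}\t{score:.6f}\t{rank}\n")
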