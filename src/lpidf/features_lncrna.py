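"""k-mer nucleotide composition features for lncRNA sequences.

A sequence of length ``x`` has ``x - k + 1`` overlapping windows of length
``k`` (stride 1).  The composition vector is the relative frequency of each of
the ``4**k`` possible k-mers, indexed lexicographically with A < C < G < T,
so for the default ``k = 4`` each lncRNA maps to a 256-dimensional vector
summing to 1.  Sequences shorter than ``k`` yield the all-zero vector with a
logged warning.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from lpidf.io_data import SequenceRecord

logger = logging.getLogger(__name__)

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer under A<C<G<T (AAAA=0, ..., TTTT=255)."""
    idx = 0
    for c in kmer:
        idx = idx * 4 + _NT_CODE[c]
    return idx


def kmer_names(k: int) -> list[str]:
    """All 4**k k-mers in index order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def kmer_composition(seq: str, k: int = 4) -> np.ndarray:
    """Relative k-mer frequencies of a canonical nucleotide sequence.

    Parameters
    ----------
    seq:
        Canonicalized nucleotide string (A/C/G/T only).
    k:
        Window size, default 4 (256 features).

    Returns
    -------
    Vector of length ``4**k`` of nonnegative fractions summing to 1, or the
    all-zero vector when ``len(seq) < k``.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    vec = np.zeros(4**k, dtype=np.float64)
    n_windows = len(seq) - k + 1
    if n_windows <= 0:
        logger.warning("sequence of length %d shorter than k=%d; zero vector", len(seq), k)
        return vec
    codes = np.fromiter((_NT_CODE[c] for c in seq), dtype=np.int64, count=len(seq))
    # rolling polynomial index over the window, base 4
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = np.correlate(codes, powers, mode="valid")
    np.add.at(vec, idx, 1.0)
    return vec / n_windows


def featurize_lncrnas(records: Sequence[SequenceRecord], k: int = 4) -> np.ndarray:
    """Stack composition vectors for a batch of records (rows follow input order)."""
    return np.vstack([kmer_composition(r.sequence, k) for r in records]) if records else np.zeros((0, 4**k))


def write_composition_tsv(
    path: str | Path, records: Sequence[SequenceRecord], matrix: np.ndarray, k: int = 4
) -> None:
    """Write a composition matrix as TSV with one named k-mer per column."""
    names = kmer_names(k)
    with open(path, "w") as handle:
        handle.write("id\t" + "\t".join(names) + "\n")
        for rec, row in zip(records, matrix):
            handle.write(rec.id + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
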