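"""Protein sequence embeddings: sliding-window segmentation, segment hashing,
and an autoencoder bottleneck.

A protein of length ``L`` is cut into the ``L - K + 1`` overlapping segments
of window size ``K`` (default 3).  Each segment is hashed to an integer in
``[0, vocab_size)`` by the polynomial

    h(s) = ( sum_i code(s_i) * 31**i ) mod vocab_size

where ``code`` is the fixed alphabetical index of the residue (A=0, C=1, ...,
Y=19; a dedicated code 20 for the optional "unknown" residue X).  The hash
sequence is padded/truncated to a fixed length ``M``, scaled to [0, 1], and an
encoder-decoder network trained to reconstruct these vectors provides the
low-dimensional embedding: the hidden bottleneck activations are the protein
feature vector.

The encoder-decoder is a feed-forward autoencoder with a single hidden layer
(M -> d_p -> M) trained under squared-error loss; training is fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from lpidf.io_data import AA_ORDER, UNKNOWN_AA_CODE, SequenceRecord, ValidationError

_AA_CODE = {aa: i for i, aa in enumerate(AA_ORDER)}
_AA_CODE["X"] = UNKNOWN_AA_CODE  # canonicalized unknown residue

#: default hash vocabulary size; prime, to spread collisions
DEFAULT_VOCAB_SIZE = 8191
#: default sliding-window size over amino acids
DEFAULT_WINDOW = 3


@dataclass(frozen=True)
class SegmentHashSequence:
    """Ordered segment hashes for one protein."""

    hashes: tuple[int, ...]
    K: int
    source_id: str


@dataclass(frozen=True)
class EncoderSpec:
    """Autoencoder configuration.

    ``input_length`` is the fixed padded length M; ``embedding_dim`` the
    bottleneck width d_p (must be smaller than M so the hidden layer is an
    actual bottleneck); ``epochs``, ``learning_rate`` and ``batch_size`` are
    ordinary training knobs; ``seed`` makes training reproducible.
    """

    input_length: int = 1024
    embedding_dim: int = 544
    epochs: int = 100
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.input_length <= 0 or self.embedding_dim <= 0 or self.epochs <= 0:
            raise ValueError("input_length, embedding_dim and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.embedding_dim >= self.input_length:
            raise ValueError(
                f"embedding_dim ({self.embedding_dim}) must be smaller than "
                f"input_length ({self.input_length})"
            )


@dataclass(frozen=True)
class ProteinEmbedding:
    values: np.ndarray
    source_id: str


def segment_sequence(seq: str, K: int, *, source_id: str = "?") -> list[str]:
    """The L - K + 1 overlapping substrings of length K, in order."""
    L = len(seq)
    if K < 1:
        raise ValidationError(f"window size must be >= 1, got {K}")
    if K > L:
        raise ValidationError(
            f"protein {source_id!r}: window size {K} exceeds sequence length {L}"
        )
    return [seq[i : i + K] for i in range(L - K + 1)]


def hash_segments(
    segments: Sequence[str],
    vocab_size: int = DEFAULT_VOCAB_SIZE,
    *,
    source_id: str = "?",
) -> SegmentHashSequence:
    """Deterministically hash same-length segments into ``[0, vocab_size)``."""
    if vocab_size < 2:
        raise ValueError(f"vocab_size must be >= 2, got {vocab_size}")
    if not segments:
        raise ValidationError(f"protein {source_id!r}: no segments to hash")
    K = len(segments[0])
    if any(len(s) != K for s in segments):
        raise ValidationError("segments must all have the same length")
    hashes = []
    for seg in segments:
        h = 0
        for i, c in enumerate(seg):
            if c not in _AA_CODE:
                raise ValidationError(
                    f"protein {source_id!r}: unrecognized residue {c!r}"
                )
            h += _AA_CODE[c] * 31**i
        hashes.append(h % vocab_size)
    return SegmentHashSequence(tuple(hashes), K, source_id)


def pad_or_truncate(
    hashes: SegmentHashSequence,
    M: int,
    pad_value: int = 0,
    *,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
) -> np.ndarray:
    """Fixed-length numeric vector from a hash sequence, scaled to [0, 1].

    Real hashes are shifted to ``[1, vocab_size]`` so the pad value 0 stays
    distinguishable, then divided by ``vocab_size``.  Longer sequences keep
    their first ``M`` hashes; shorter ones are right-padded.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    shifted = np.asarray(hashes.hashes[:M], dtype=np.float64) + 1.0
    vec = np.full(M, float(pad_value), dtype=np.float64)
    vec[: len(shifted)] = shifted
    return vec / vocab_size


class ProteinEncoder:
    """Trained encoder half of the reconstruction autoencoder.

    Wraps a single-hidden-layer network trained to reproduce its input; the
    hidden activations are the embedding.  ``loss_curve`` records the
    squared-error training loss per epoch.
    """

    def __init__(self, net: MLPRegressor, spec: EncoderSpec):
        self._net = net
        self.spec = spec
        self.loss_curve: list[float] = list(net.loss_curve_)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.spec.input_length:
            raise ValidationError(
                f"expected input of width {self.spec.input_length}, got shape {X.shape}"
            )
        hidden = X @ self._net.coefs_[0] + self._net.intercepts_[0]
        np.maximum(hidden, 0.0, out=hidden)  # relu, matching the trained net
        return hidden


def fit_autoencoder(X: np.ndarray, spec: EncoderSpec) -> ProteinEncoder:
    """Train the reconstruction autoencoder and return its encoder half."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("autoencoder training needs a 2-D matrix with >= 2 rows")
    if X.shape[1] != spec.input_length:
        raise ValidationError(
            f"training matrix width {X.shape[1]} != spec.input_length {spec.input_length}"
        )
    if not np.isfinite(X).all():
        raise ValidationError("autoencoder input contains non-finite values")
    net = MLPRegressor(
        hidden_layer_sizes=(spec.embedding_dim,),
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=min(spec.batch_size, X.shape[0]),
        max_iter=spec.epochs,
        shuffle=True,
        random_state=spec.seed,
        tol=0.0,  # run all epochs; reproducibility over early exit
        n_iter_no_change=spec.epochs,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # a fixed epoch budget is intentional; the optimizer need not converge
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(X, X)
    return ProteinEncoder(net, spec)


def embed_proteins(
    encoder: ProteinEncoder, X: np.ndarray, ids: Sequence[str] | None = None
) -> list[ProteinEmbedding]:
    """One embedding per row of X, in order."""
    H = encoder.transform(X)
    if ids is None:
        ids = [str(i) for i in range(H.shape[0])]
    return [ProteinEmbedding(row, pid) for row, pid in zip(H, ids)]


def hash_matrix(
    records: Sequence[SequenceRecord],
    K: int = DEFAULT_WINDOW,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
    M: int = 1024,
) -> np.ndarray:
    """Segment, hash and pad a batch of proteins into the autoencoder input."""
    rows = []
    for rec in records:
        segs = segment_sequence(rec.sequence, K, source_id=rec.id)
        hashes = hash_segments(segs, vocab_size, source_id=rec.id)
        rows.append(pad_or_truncate(hashes, M, vocab_size=vocab_size))
    return np.vstack(rows) if rows else np.zeros((0, M))


def featurize_proteins(
    records: Sequence[SequenceRecord],
    spec: EncoderSpec,
    K: int = DEFAULT_WINDOW,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
) -> tuple[np.ndarray, ProteinEncoder]:
    """Full protein featurization: hash matrix -> autoencoder -> embeddings.

    Returns the embedding matrix (rows follow input order) and the trained
    encoder, so new proteins can be embedded into the same space.
    """
    X = hash_matrix(records, K=K, vocab_size=vocab_size, M=spec.input_length)
    encoder = fit_autoencoder(X, spec)
    return encoder.transform(X), encoder
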