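import numpy as np
import pytest
from hypothesis import settings

from lpidf.cascade_forest import CascadeConfig
from lpidf.evaluation import PipelineConfig
from lpidf.features_protein import EncoderSpec
from lpidf.synthetic_data import SyntheticSpec, generate_dataset

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


def make_separable_toy(n: int = 200, d: int = 10, seed: int = 0):
    """Two well-separated Gaussian classes (means +/-3 sigma)."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(3.0, 1.0, (n // 2, d)), rng.normal(-3.0, 1.0, (n - n // 2, d))]
    )
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    return X, y


@pytest.fixture(scope="session")
def separable_toy():
    return make_separable_toy()


def light_cascade(seed: int = 0, **kw) -> CascadeConfig:
    """Small cascade for unit tests: fewer trees, shallow."""
    defaults = dict(max_layers=2, n_trees=15, oof_folds=2, seed=seed)
    defaults.update(kw)
    return CascadeConfig(**defaults)


def light_pipeline(seed: int = 0, **kw) -> PipelineConfig:
    """Cheap full-pipeline configuration for small fixtures."""
    defaults = dict(
        encoder=EncoderSpec(input_length=64, embedding_dim=8, epochs=10, seed=seed),
        cascade=light_cascade(seed=seed, max_layers=1),
        n_folds=2,
        base_seed=seed,
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


def tiny_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """Small synthetic dataset spec for fast end-to-end tests."""
    defaults = dict(
        n_lncrnas=30,
        n_proteins=8,
        lncrna_length_range=(80, 120),
        protein_length_range=(70, 100),
        n_motif_classes=2,
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(tiny_spec(seed=3))


# --- independent oracles ---------------------------------------------------


def auc_oracle(labels, scores) -> float:
    """All-pairs comparison: P(random positive outscores random negative),
    ties counted half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def aupr_oracle(labels, scores) -> float:
    """Brute-force threshold sweep: at every distinct score threshold compute
    (recall, precision), then sum the step areas (R_n - R_{n-1}) * P_n."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def kmer_oracle(seq: str, k: int) -> np.ndarray:
    """Dictionary-counting k-mer composition, independent of the vectorized
    implementation."""
    import itertools

    names = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    counts = {name: 0 for name in names}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    total = sum(counts.values())
    vec = np.array([counts[name] for name in names], dtype=float)
    return vec / total if total else vec


def segment_hash_oracle(segment: str, vocab_size: int) -> int:
    """Polynomial hash recomputed from the amino-acid alphabetical codes."""
    order = "ACDEFGHIKLMNPQRSTVWY"
    h = 0
    for i, c in enumerate(segment):
        h += order.index(c) * 31**i
    return h % vocab_size
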