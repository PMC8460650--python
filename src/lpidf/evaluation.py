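"""Cross-validation, negative sampling, metrics and ranking.

Three five-fold protocols probe different prediction regimes on the bipartite
interaction matrix Y:

* CV1 masks whole lncRNA rows — the model must score interactions for
  lncRNAs with no known partners (cold start on lncRNAs);
* CV2 masks whole protein columns (cold start on proteins);
* CV3 masks individual pairs (the transductive setting).

Because the zero entries of Y are unknown rather than verified negatives,
each experiment samples as many presumed negatives as there are positives,
uniformly from the zero entries, so training and test sets are balanced.
Under CV1/CV2 the test negatives are drawn from the masked rows/columns so
the cold-start test set is itself balanced.  Experiments are repeated with
fresh negative samples and fresh splits; metrics are averaged fold-first,
then across repeats, reported as mean +/- standard deviation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from lpidf.cascade_forest import CascadeConfig, CascadeModel, fit_cascade, predict_proba
from lpidf.features_lncrna import featurize_lncrnas
from lpidf.features_protein import EncoderSpec, featurize_proteins
from lpidf.io_data import Dataset, InteractionMatrix, ValidationError

CV_SCHEMES = ("cv1", "cv2", "cv3")

Pair = tuple[int, int]
LabeledPair = tuple[int, int, int]


@dataclass
class CVSplit:
    """One fold: disjoint train/test lists of (row, column, label) triples."""

    fold_id: int
    train_pairs: list[LabeledPair]
    test_pairs: list[LabeledPair]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int


def sample_negatives(
    Y: InteractionMatrix,
    n: int,
    exclude: set[Pair] | None = None,
    seed: int = 0,
    *,
    rows: Sequence[int] | None = None,
    cols: Sequence[int] | None = None,
) -> list[Pair]:
    """Draw ``n`` distinct zero-entry pairs uniformly without replacement.

    ``rows``/``cols`` optionally restrict the candidate pool (used to keep
    cold-start test folds balanced within the masked rows or columns);
    ``exclude`` removes specific pairs from the pool.
    """
    exclude = exclude or set()
    mat = Y.Y
    zr, zc = np.nonzero(mat == 0)
    pool = list(zip(zr.tolist(), zc.tolist()))
    if rows is not None:
        rset = set(rows)
        pool = [p for p in pool if p[0] in rset]
    if cols is not None:
        cset = set(cols)
        pool = [p for p in pool if p[1] in cset]
    if exclude:
        pool = [p for p in pool if p not in exclude]
    if n > len(pool):
        raise ValidationError(
            f"requested {n} negatives but only {len(pool)} unknown pairs available "
            f"(deficit {n - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in chosen]


def _positives(Y: InteractionMatrix) -> list[Pair]:
    return Y.positive_pairs()


def _group_folds(n_items: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n_items)
    return np.array_split(perm, n_folds)


def make_cv_splits(
    Y: InteractionMatrix, scheme: str, n_folds: int = 5, seed: int = 0
) -> list[CVSplit]:
    """Build balanced train/test folds for one of the three CV protocols.

    CV1 partitions lncRNA rows into ``n_folds`` groups; each fold's test set
    is the masked rows' positives plus an equal number of negatives sampled
    from those rows, and its training set is the remaining rows' positives
    plus matched negatives.  CV2 is the same over protein columns.  CV3
    samples one balanced labeled pair set and partitions it (stratified) into
    folds.  Folds are exhaustive and disjoint; no CV1 test row (CV2 test
    column) ever appears among that fold's training pairs.
    """
    scheme = scheme.lower()
    if scheme not in CV_SCHEMES:
        raise ValueError(f"scheme must be one of {CV_SCHEMES}, got {scheme!r}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    positives = _positives(Y)
    if not positives:
        raise ValidationError("interaction matrix has no positive pairs")

    if scheme in ("cv1", "cv2"):
        axis_size = Y.shape[0] if scheme == "cv1" else Y.shape[1]
        if axis_size < n_folds:
            raise ValidationError(
                f"{scheme} needs at least {n_folds} "
                f"{'rows' if scheme == 'cv1' else 'columns'}, have {axis_size}"
            )
        groups = _group_folds(axis_size, n_folds, rng)
        splits = []
        for fold_id, group in enumerate(groups):
            test_units = set(group.tolist())
            if scheme == "cv1":
                test_pos = [p for p in positives if p[0] in test_units]
                train_pos = [p for p in positives if p[0] not in test_units]
                test_neg = sample_negatives(
                    Y, len(test_pos), seed=int(rng.integers(2**31)), rows=sorted(test_units)
                )
                train_units = [r for r in range(Y.shape[0]) if r not in test_units]
                train_neg = sample_negatives(
                    Y, len(train_pos), seed=int(rng.integers(2**31)), rows=train_units
                )
            else:
                test_pos = [p for p in positives if p[1] in test_units]
                train_pos = [p for p in positives if p[1] not in test_units]
                test_neg = sample_negatives(
                    Y, len(test_pos), seed=int(rng.integers(2**31)), cols=sorted(test_units)
                )
                train_units = [c for c in range(Y.shape[1]) if c not in test_units]
                train_neg = sample_negatives(
                    Y, len(train_pos), seed=int(rng.integers(2**31)), cols=train_units
                )
            train = [(r, c, 1) for r, c in train_pos] + [(r, c, 0) for r, c in train_neg]
            test = [(r, c, 1) for r, c in test_pos] + [(r, c, 0) for r, c in test_neg]
            splits.append(CVSplit(fold_id, train, test))
        return splits

    # CV3: balanced labeled pool, stratified partition over pairs
    negatives = sample_negatives(Y, len(positives), seed=int(rng.integers(2**31)))
    pool = [(r, c, 1) for r, c in positives] + [(r, c, 0) for r, c in negatives]
    labels = np.array([lab for _, _, lab in pool])
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    splits = []
    for fold_id, (tr, te) in enumerate(skf.split(np.zeros(len(pool)), labels)):
        splits.append(
            CVSplit(fold_id, [pool[i] for i in tr], [pool[i] for i in te])
        )
    return splits


def compute_point_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, accuracy and F1 from a confusion table.

    Degenerate denominators (no predicted positives, or no actual positives)
    yield 0 with a warning so that fold averaging stays defined.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    total = tp + fp + tn + fn
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn("no predicted positives; precision set to 0", stacklevel=2)
        precision = 0.0
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        warnings.warn("no actual positives; recall set to 0", stacklevel=2)
        recall = 0.0
    accuracy = (tp + tn) / total if total > 0 else 0.0
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
    return {"precision": precision, "recall": recall, "accuracy": accuracy, "f1": f1}


def compute_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based area under the ROC curve (ties counted half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def compute_aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve.

    Step-wise rule sum_n (R_n - R_{n-1}) * P_n over descending score
    thresholds — no linear interpolation between PR points.
    """
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValidationError("AUPR needs at least one positive")
    return float(average_precision_score(labels, scores))


@dataclass
class MetricsReport:
    """Per-repeat and aggregated evaluation metrics."""

    scheme: str
    n_folds: int
    per_repeat: list[dict[str, float]]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    METRICS = ("precision", "recall", "accuracy", "f1", "auc", "aupr")

    def __post_init__(self) -> None:
        if not self.mean:
            for m in self.METRICS:
                vals = [r[m] for r in self.per_repeat]
                self.mean[m] = float(np.mean(vals))
                self.std[m] = float(np.std(vals))

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    def summary(self) -> pd.DataFrame:
        """One row per repeat plus mean/std rows."""
        df = pd.DataFrame(self.per_repeat)
        df.index = [f"repeat_{i}" for i in range(len(df))]
        df.loc["mean"] = [self.mean[m] for m in df.columns]
        df.loc["std"] = [self.std[m] for m in df.columns]
        return df

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index_label="run")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "scheme": self.scheme,
                    "n_folds": self.n_folds,
                    "n_repeats": self.n_repeats,
                    "mean": self.mean,
                    "std": self.std,
                    "per_repeat": self.per_repeat,
                },
                fh,
                indent=2,
            )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration: featurization + cascade + CV settings."""

    kmer_k: int = 4
    protein_window: int = 3
    vocab_size: int = 8191
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    n_folds: int = 5
    base_seed: int = 0


def featurize_dataset(
    dataset: Dataset, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """lncRNA composition matrix and protein embedding matrix for a dataset.

    The autoencoder is trained once per dataset on all protein hash vectors
    (unsupervised — no interaction labels are involved).
    """
    L = featurize_lncrnas(dataset.lncrnas, k=config.kmer_k)
    spec = replace(config.encoder, seed=config.base_seed)
    P, _ = featurize_proteins(
        dataset.proteins, spec, K=config.protein_window, vocab_size=config.vocab_size
    )
    return L, P


def pair_features(
    L: np.ndarray, P: np.ndarray, pairs: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Concatenated lncRNA + protein feature vectors for candidate pairs."""
    rows = np.array([p[0] for p in pairs], dtype=int)
    cols = np.array([p[1] for p in pairs], dtype=int)
    return np.hstack([L[rows], P[cols]])


def _fold_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    pred = (scores >= threshold).astype(int)
    counts = ConfusionCounts(
        TP=int(((pred == 1) & (y_true == 1)).sum()),
        FP=int(((pred == 1) & (y_true == 0)).sum()),
        TN=int(((pred == 0) & (y_true == 0)).sum()),
        FN=int(((pred == 0) & (y_true == 1)).sum()),
    )
    metrics = compute_point_metrics(counts)
    metrics["auc"] = compute_auc(y_true, scores)
    metrics["aupr"] = compute_aupr(y_true, scores)
    return metrics


def run_cv_experiment(
    dataset: Dataset,
    scheme: str,
    repeats: int = 20,
    config: PipelineConfig | None = None,
) -> MetricsReport:
    """Repeated cross-validated evaluation of the full pipeline.

    Each repeat draws a fresh negative sample and fresh folds (seeded by
    ``base_seed + repeat``), trains a cascade per fold, scores the fold's
    test pairs, and averages the six metrics over folds; the report carries
    every repeat plus mean and standard deviation.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    config = config or PipelineConfig()
    L, P = featurize_dataset(dataset, config)
    Y = dataset.interactions

    per_repeat = []
    for rep in range(repeats):
        rep_seed = config.base_seed + rep
        splits = make_cv_splits(Y, scheme, n_folds=config.n_folds, seed=rep_seed)
        fold_rows = []
        for split in splits:
            cascade_seed = (config.base_seed + 104729 * rep + 31 * split.fold_id) % (
                2**31
            )
            cc = replace(config.cascade, seed=cascade_seed)
            X_tr = pair_features(L, P, [(r, c) for r, c, _ in split.train_pairs])
            y_tr = np.array([lab for _, _, lab in split.train_pairs])
            X_te = pair_features(L, P, [(r, c) for r, c, _ in split.test_pairs])
            y_te = np.array([lab for _, _, lab in split.test_pairs])
            model = fit_cascade(X_tr, y_tr, cc)
            scores = predict_proba(model, X_te)
            fold_rows.append(_fold_metrics(y_te, scores))
        per_repeat.append(
            {m: float(np.mean([f[m] for f in fold_rows])) for m in fold_rows[0]}
        )
    return MetricsReport(scheme=scheme, n_folds=config.n_folds, per_repeat=per_repeat)


def rank_unknown_pairs(
    model: CascadeModel,
    dataset: Dataset,
    L: np.ndarray,
    P: np.ndarray,
    restrict: str | None = None,
) -> list[tuple[str, str, float, int]]:
    """Score and rank every unknown (zero-entry) pair, descending.

    ``restrict`` limits the candidates to one lncRNA row or protein column
    (given by id), as in per-entity case studies.  Ties are broken by
    (lncrna_id, protein_id) lexicographic order; ranks are 1-based.
    """
    Y = dataset.interactions
    zr, zc = np.nonzero(Y.Y == 0)
    pairs = list(zip(zr.tolist(), zc.tolist()))
    if restrict is not None:
        if restrict in Y.lncrna_ids:
            row = Y.row_of(restrict)
            pairs = [p for p in pairs if p[0] == row]
        elif restrict in Y.protein_ids:
            col = Y.col_of(restrict)
            pairs = [p for p in pairs if p[1] == col]
        else:
            raise ValidationError(f"restrict id {restrict!r} not found in dataset")
    if not pairs:
        return []
    X = pair_features(L, P, pairs)
    scores = predict_proba(model, X)
    entries = [
        (Y.lncrna_ids[r], Y.protein_ids[c], float(s))
        for (r, c), s in zip(pairs, scores)
    ]
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return [(lid, pid, s, i + 1) for i, (lid, pid, s) in enumerate(entries)]


def top_n_true_fraction(
    ranked: Sequence[tuple[str, str, float, int]],
    truth: dict[tuple[str, str], int],
    N: int,
) -> float:
    """Percentage of true interactions among the top-N ranked pairs."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > len(ranked):
        raise ValidationError(f"N={N} exceeds ranking length {len(ranked)}")
    hits = sum(truth.get((lid, pid), 0) for lid, pid, _, _ in ranked[:N])
    return 100.0 * hits / N
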