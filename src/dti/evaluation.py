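"""Negative sampling, ten-fold cross-validation, metrics and ranking.

Known interactions are the positives; negatives are drawn uniformly
without replacement from the zero entries of X at a chosen
positive:negative ratio (1:1, 1:3, 1:5, 1:10).  The sampled pair set is
split into ten label-stratified folds; each fold is scored by a model
trained on the other nine.  Per-fold metrics are the confusion-based
five (sensitivity, specificity, precision, F1, MCC) plus AUC-ROC and
AUPR; fold vectors of two models are compared with a paired two-sided
t-test.  Unsampled zero pairs never enter training or testing — they
are scored only when ranking novel interaction candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import (
    DimensionError,
    MetricError,
    SamplingError,
    ValidationError,
)
from .labeling import assign_cluster_labels, select_cluster_count
from .embedding import TripletConfig, train_embedder
from .predictor import (
    PredictorConfig,
    build_predictor,
    initial_bias,
    train_predictor,
)
from .preprocess import build_feature_matrices

__all__ = [
    "SamplingSpec",
    "FoldSplit",
    "MetricsRow",
    "EvaluationReport",
    "TTestResult",
    "sample_negative_pairs",
    "make_cv_folds",
    "compute_metrics",
    "run_cross_validation",
    "paired_t_test",
    "rank_novel_interactions",
]

N_FOLDS = 10

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f1", "mcc",
                "auc_roc", "aupr")


@dataclass
class SamplingSpec:
    """Negative-sampling design: r negatives per positive, seeded."""

    ratio: int = 3
    seed: int = 0

    def validate(self) -> "SamplingSpec":
        if self.ratio < 1:
            raise ValidationError("ratio must be >= 1")
        return self


@dataclass
class FoldSplit:
    """Fold id (0..9) per sampled pair; disjoint, sizes differ by <= 1."""

    fold_ids: np.ndarray

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_ids == fold)


@dataclass
class MetricsRow:
    """One fold's confusion counts and the seven metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    auc_roc: float
    aupr: float
    threshold: float
    flags: list = field(default_factory=list)


@dataclass
class EvaluationReport:
    """Per-fold and aggregate metrics of one cross-validated run."""

    mode: str
    ratio: int
    seed: int
    folds: list
    mean: dict
    std: dict
    threshold: float

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "ratio": self.ratio,
            "seed": self.seed,
            "threshold": self.threshold,
            "folds": [
                {"fold": i, **asdict(row)} for i, row in enumerate(self.folds)
            ],
            "mean": self.mean,
            "std": self.std,
        }


@dataclass
class TTestResult:
    t: float
    p_value: float
    degenerate: bool = False


def sample_negative_pairs(X, spec: SamplingSpec):
    """Draw ratio × positives zero-entry pairs uniformly without replacement.

    Returns an integer array of (drug_index, target_index) rows, sorted
    deterministically by the seeded draw.
    """
    spec.validate()
    X = np.asarray(X)
    pos_count = int(np.sum(X == 1))
    zeros = np.argwhere(X == 0)
    wanted = spec.ratio * pos_count
    if pos_count == 0:
        raise SamplingError("interaction matrix has no positives")
    if zeros.shape[0] < wanted:
        raise SamplingError(
            f"need {wanted} negatives but only {zeros.shape[0]} zero entries exist"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    take = rng.choice(zeros.shape[0], size=wanted, replace=False)
    return zeros[take]


def make_cv_folds(labels, seed: int) -> FoldSplit:
    """Ten label-stratified folds via seeded shuffle + round-robin.

    Each fold's positive count is within one pair of every other fold's,
    and total fold sizes differ by at most one (the negative round-robin
    starts where the positive remainder stopped).
    """
    labels = np.asarray(labels)
    if labels.size < N_FOLDS:
        raise ValidationError(f"need at least {N_FOLDS} pairs for {N_FOLDS} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    fold_ids = np.empty(labels.size, dtype=int)
    offset = 0
    for cls in (1, 0):  # positives first so negatives fill the remainder folds
        members = np.flatnonzero(labels == cls)
        if members.size == 0:
            continue
        perm = rng.permutation(members)
        fold_ids[perm] = (np.arange(perm.size) + offset) % N_FOLDS
        offset = (offset + perm.size) % N_FOLDS
    return FoldSplit(fold_ids=fold_ids)


def _confusion(labels, scores, threshold):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsRow:
    """Confusion metrics at a threshold plus threshold-free AUC-ROC/AUPR.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), F1 = harmonic mean, MCC from the 2×2 table.
    AUC-ROC follows the rank (Mann-Whitney) formulation with tied scores
    given half credit; AUPR is the area under the precision-recall step
    curve.  Undefined precision (TP+FP=0) is reported as 0 with a flag.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size or labels.size < 1:
        raise ValidationError("labels and scores must have equal length >= 1")
    if np.unique(labels).size < 2:
        raise MetricError("AUC-ROC/AUPR/MCC need both classes present")

    tp, fp, tn, fn = _confusion(labels, scores, threshold)
    flags = []
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    if tp + fp == 0:
        precision = 0.0
        flags.append("precision_undefined")
    else:
        precision = tp / (tp + fp)
    if precision + sensitivity == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
        flags.append("mcc_undefined")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return MetricsRow(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=float(sensitivity), specificity=float(specificity),
        precision=float(precision), f1=float(f1), mcc=float(mcc),
        auc_roc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        threshold=float(threshold), flags=flags,
    )


def paired_t_test(metric_a, metric_b) -> TTestResult:
    """Paired two-sided t-test on fold-wise metric differences.

    Zero-variance differences are degenerate: p = 1 when the mean
    difference is also zero (identical vectors), p = 0 otherwise.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size != b.size:
        raise ValidationError("fold-metric vectors must have equal length")
    if a.size < 2:
        raise ValidationError("need at least two folds")
    d = a - b
    if np.std(d) == 0.0:
        if np.mean(d) == 0.0:
            return TTestResult(t=0.0, p_value=1.0, degenerate=True)
        return TTestResult(t=np.inf * np.sign(np.mean(d)), p_value=0.0,
                           degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(t=float(t), p_value=float(p), degenerate=False)


def rank_novel_interactions(score_matrix, X, threshold: float = 0.9,
                            drug_ids=None, target_ids=None):
    """Candidate novel interactions: high-scoring pairs not already known.

    Returns (drug_id, target_id, score) rows with score >= threshold and
    X entry 0, sorted by descending score with ascending (drug_id,
    target_id) tie-break.  Known positives are excluded regardless of
    score.
    """
    S = np.asarray(score_matrix, dtype=float)
    X = np.asarray(X)
    if S.shape != X.shape:
        raise DimensionError(f"score matrix {S.shape} vs X {X.shape}")
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    keep = (S >= threshold) & (X == 0)
    rows, cols = np.nonzero(keep)
    out = []
    for i, j in zip(rows, cols):
        d = drug_ids[i] if drug_ids is not None else int(i)
        t = target_ids[j] if target_ids is not None else int(j)
        out.append((d, t, float(S[i, j])))
    out.sort(key=lambda r: (-r[2], r[0], r[1]))
    return out


def _derive_seed(master, stream):
    return int(np.random.SeedSequence([master, stream]).generate_state(1)[0]
               % (2 ** 31))


def run_cross_validation(bundle, mode: str, spec: SamplingSpec, *,
                         predictor_config: PredictorConfig = None,
                         triplet_config: TripletConfig = None,
                         k_drug: int = None, k_target: int = None,
                         threshold: float = 0.5,
                         shuffle_labels: bool = False) -> EvaluationReport:
    """Ten-fold cross-validated evaluation of one pipeline on one bundle.

    mode "dedti": pair features are concatenated raw feature-matrix rows
    (input length m+n).  mode "iedti": feature matrices are clustered
    into pseudo-labels, triplet embedders are trained per side (on the
    feature matrices only — X never enters the feature space), and pair
    features are concatenated embeddings.  For each fold a fresh
    classifier (bias preset from the training fold's class counts) is
    trained on the other nine folds and scores the held-out fold.

    ``shuffle_labels=True`` permutes the sampled pair labels before
    folding — the chance-level control.
    """
    if mode not in ("dedti", "iedti"):
        raise ValidationError(f"unknown mode {mode!r}")
    spec.validate()
    D, T = build_feature_matrices(bundle)

    if mode == "iedti":
        tcfg = triplet_config or TripletConfig(seed=_derive_seed(spec.seed, 10))
        kd = k_drug or select_cluster_count(D, 2, min(8, bundle.m),
                                            _derive_seed(spec.seed, 11))
        kt = k_target or select_cluster_count(T, 2, min(8, bundle.n),
                                              _derive_seed(spec.seed, 12))
        drug_labels = assign_cluster_labels(D, kd, _derive_seed(spec.seed, 13))
        target_labels = assign_cluster_labels(T, kt, _derive_seed(spec.seed, 14))
        drug_vecs = train_embedder(D, drug_labels, tcfg, "drug").transform(D).values
        target_vecs = train_embedder(T, target_labels, tcfg, "target").transform(T).values
    else:
        drug_vecs, target_vecs = D.values, T.values

    X = bundle.X
    positives = np.argwhere(X == 1)
    negatives = sample_negative_pairs(X, spec)
    pairs = np.vstack([positives, negatives])
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    if shuffle_labels:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 99]))
        labels = rng.permutation(labels)
    split = make_cv_folds(labels, spec.seed)

    input_length = drug_vecs.shape[1] + target_vecs.shape[1]
    base = predictor_config or PredictorConfig(input_length=input_length)
    features = np.concatenate(
        [drug_vecs[pairs[:, 0]], target_vecs[pairs[:, 1]]], axis=1)

    fold_rows = []
    for fold in range(N_FOLDS):
        test_idx = split.fold_indices(fold)
        train_idx = np.setdiff1d(np.arange(labels.size), test_idx)
        y_train = labels[train_idx]
        cfg = PredictorConfig(**{
            **asdict(base),
            "input_length": input_length,
            "initial_bias": initial_bias(int(y_train.sum()),
                                         int((1 - y_train).sum())),
            "seed": _derive_seed(spec.seed, 20 + fold),
        })
        cfg.conv_filters = tuple(cfg.conv_filters)
        model = build_predictor(cfg)
        train_predictor(model, (features[train_idx], y_train), cfg)
        scores = model.predict(features[test_idx])
        fold_rows.append(compute_metrics(labels[test_idx], scores, threshold))

    mean = {k: float(np.mean([getattr(r, k) for r in fold_rows]))
            for k in METRIC_NAMES}
    std = {k: float(np.std([getattr(r, k) for r in fold_rows], ddof=1))
           for k in METRIC_NAMES}
    return EvaluationReport(mode=mode, ratio=spec.ratio, seed=spec.seed,
                            folds=fold_rows, mean=mean, std=std,
                            threshold=threshold)
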