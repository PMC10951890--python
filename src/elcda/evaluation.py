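"""Balanced negative sampling, leakage-safe cross-validation and metrics.

Known associations are the positives; an equal number of unobserved
circRNA-disease cells is drawn uniformly as negatives, and the balanced set
is split into stratified folds.  For each fold, every quantity derived from
association edges — metapath counts, GIP/functional similarity, the
integrated SC/SD matrices, the factorisation indicator and the GraphSAGE
edge set — is recomputed from training-fold positives only, unless
``paper_mode`` is set, which computes similarities once from all positives
(the protocol most published link-prediction studies appear to use).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .ensemble import prediction_table
from .hetnet import HeteroNetwork
from .pipeline import AssociationPipeline
from .similarity import DiseaseDAG, ExpressionProfiles, SimilarityConfig, compute_similarity_bundle

METRIC_KEYS = ("accuracy", "recall", "precision", "f1", "auc", "aupr")


def sample_negatives(net: HeteroNetwork, k: int, seed: int = 0) -> np.ndarray:
    """k uniform draws without replacement from unobserved (c, d) cells."""
    zeros = np.argwhere(net.A_CD == 0)
    if k > len(zeros):
        raise ValueError(f"requested {k} negatives but only {len(zeros)} "
                         f"unobserved cells exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(zeros), size=k, replace=False)
    return zeros[idx]


def kfold_split(y: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (0..k-1) per sample."""
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k-fold cross-validation needs k >= 2")
    if (y == 1).sum() < k:
        raise ValueError(f"need at least {k} positives for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> dict:
    """Confusion counts at the threshold plus Accuracy/Recall/Precision/F1,
    AUC (rank statistic) and AUPR (trapezoidal precision-recall integral)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = p >= threshold
    tp = int(((y == 1) & pred).sum())
    tn = int(((y == 0) & ~pred).sum())
    fp = int(((y == 0) & pred).sum())
    fn = int(((y == 1) & ~pred).sum())
    acc = (tp + tn) / len(y) if len(y) else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    if len(np.unique(y)) < 2:
        auc = aupr = None
    else:
        auc = float(roc_auc_score(y, p))
        pr, rc, _ = precision_recall_curve(y, p)
        aupr = float(-np.trapezoid(pr, rc))  # recall is decreasing
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn, "accuracy": acc,
            "recall": rec, "precision": prec, "f1": f1, "auc": auc, "aupr": aupr}


@dataclass
class MetricReport:
    """Per-fold metrics with mean and standard deviation."""

    per_fold: list[dict]
    mean: dict = field(init=False)
    sd: dict = field(init=False)

    def __post_init__(self) -> None:
        self.mean, self.sd = {}, {}
        for key in METRIC_KEYS:
            vals = [f[key] for f in self.per_fold if f[key] is not None]
            self.mean[key] = float(np.mean(vals)) if vals else None
            self.sd[key] = float(np.std(vals)) if vals else None

    def to_dict(self) -> dict:
        return {"per_fold": self.per_fold, "mean": self.mean, "sd": self.sd}

    def __str__(self) -> str:
        lines = ["metric      mean      sd"]
        for key in METRIC_KEYS:
            m, s = self.mean[key], self.sd[key]
            lines.append(f"{key:<10}  {m:.4f}    {s:.4f}" if m is not None
                         else f"{key:<10}  n/a")
        return "\n".join(lines)


def build_dataset(net: HeteroNetwork, seed: int = 0,
                  k_folds: int = 5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balanced labelled pairs (positives + sampled negatives) with folds."""
    pos = np.argwhere(net.A_CD == 1)
    neg = sample_negatives(net, len(pos), seed=seed)
    pairs = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=int),
                        np.zeros(len(neg), dtype=int)])
    folds = kfold_split(y, k=k_folds, seed=seed)
    return pairs, y, folds


def run_cv(net: HeteroNetwork,
           dag: DiseaseDAG | None = None,
           profiles: ExpressionProfiles | None = None,
           k_folds: int = 5,
           seed: int = 0,
           threshold: float = 0.5,
           paper_mode: bool = False,
           permute_labels: bool = False,
           sim_config: SimilarityConfig | None = None,
           pipeline_params: dict | None = None) -> tuple[MetricReport, pd.DataFrame]:
    """Balanced, stratified k-fold cross-validation of the full pipeline.

    Returns the aggregated :class:`MetricReport` and the prediction table of
    all held-out pairs.  ``permute_labels`` shuffles the labels (seeded)
    before splitting — a null control whose AUC should hover around 0.5.
    """
    pairs, y, folds = build_dataset(net, seed=seed, k_folds=k_folds)
    if permute_labels:
        rng = np.random.default_rng(seed + 104729)
        y = y[rng.permutation(len(y))]
        folds = kfold_split(y, k=k_folds, seed=seed)

    bundle_full = None
    if paper_mode:
        bundle_full = compute_similarity_bundle(net, dag, profiles, sim_config)

    fold_metrics, tables = [], []
    for fold in range(k_folds):
        train = folds != fold
        test = ~train
        train_pairs, train_y = pairs[train], y[train]
        test_pairs, test_y = pairs[test], y[test]

        # training-fold association matrix: positives of the training folds
        H = np.zeros((net.n_circ, net.n_disease), dtype=int)
        for (ci, dj), label in zip(train_pairs, train_y):
            if label == 1:
                H[ci, dj] = 1
        net_train = net.with_cd(H)
        bundle = bundle_full if paper_mode else compute_similarity_bundle(
            net_train, dag, profiles, sim_config)

        pipe = AssociationPipeline(random_state=seed * 10 + fold,
                                   **(pipeline_params or {}))
        pipe.fit(net_train, bundle, train_pairs, train_y)
        member = pipe.member_proba(test_pairs)
        fused = member.mean(axis=1)
        fold_metrics.append(compute_metrics(test_y, fused, threshold))
        tbl = prediction_table(net.circ_ids, net.disease_ids, test_pairs,
                               member, labels=test_y)
        tbl.insert(0, "fold", fold)
        tables.append(tbl)

    report = MetricReport(fold_metrics)
    return report, pd.concat(tables, ignore_index=True)
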