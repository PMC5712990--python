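"""Method-agnostic evaluation: pooled ROC/AUC, cost-threshold confusion
matrices, cross-validation and scripted replications.

All off-diagonal (cell, trial) decisions are pooled into one binary scoring
problem (micro-averaging); the ROC threshold sweeps the unique score values
and the AUC is the trapezoidal integral.  For the matrix-based classifier the
cells of each trial are *jointly* thresholded, which is exactly what pooling
its marginal cell posteriors implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .simulate import LabeledDataset, generate_dataset, offdiag_pairs
from .features import featurize_dataset
from .models import (
    CellBasedGraphClassifier,
    MatrixBasedGraphClassifier,
    cost_threshold,
)
from .geweke import gca_dataset_scores

__all__ = [
    "ROCCurve",
    "ConfusionReport",
    "ExperimentReport",
    "pool_cells",
    "roc_auc",
    "confusion_at_threshold",
    "crossval_cell_scores",
    "crossval_auc",
    "mismatch_auc",
    "replicate",
]


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class ConfusionReport:
    """Row-normalised 2x2 confusion in percent at a fixed threshold."""

    tp_pct: float
    fn_pct: float
    fp_pct: float
    tn_pct: float
    threshold: float
    counts: dict = field(default_factory=dict)


@dataclass
class ExperimentReport:
    method: str
    mode: str
    dataset: str
    train_dataset: str | None
    auc: float
    roc: ROCCurve
    confusion: ConfusionReport
    seed: int
    config: dict = field(default_factory=dict)
    cell_scores: np.ndarray | None = None
    truths: np.ndarray | None = None

    def summary(self) -> dict:
        return {
            "method": self.method,
            "mode": self.mode,
            "dataset": self.dataset,
            "train_dataset": self.train_dataset,
            "auc": self.auc,
            "confusion": {
                k: v
                for k, v in asdict(self.confusion).items()
                if k != "counts"
            },
            "seed": self.seed,
            "config": self.config,
        }


def pool_cells(scores: np.ndarray, truths: np.ndarray):
    """Flatten off-diagonal cells of (n, M, M) score/truth stacks."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if scores.shape != truths.shape or scores.ndim != 3:
        raise ValueError("scores and truths must be aligned (n, M, M) stacks")
    M = scores.shape[1]
    mask = ~np.eye(M, dtype=bool)
    s = scores[:, mask].ravel()
    t = truths[:, mask].ravel().astype(int)
    if not np.isfinite(s).all():
        raise ValueError("pooled scores contain non-finite values")
    return s, t


def roc_auc(scores: np.ndarray, truths: np.ndarray) -> ROCCurve:
    """Pooled (micro-averaged) ROC over all off-diagonal cells and trials."""
    s, t = pool_cells(scores, truths)
    if t.min() == t.max():
        raise ValueError("AUC undefined: pooled truth labels are single-class")
    fpr, tpr, thr = roc_curve(t, s)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(_trapezoid_auc(fpr, tpr)))


def confusion_at_threshold(
    scores: np.ndarray, truths: np.ndarray, threshold: float
) -> ConfusionReport:
    s, t = pool_cells(scores, truths)
    if s.size == 0:
        raise ValueError("empty decision pool")
    pred = (s > threshold).astype(int)
    tp = int(((pred == 1) & (t == 1)).sum())
    fn = int(((pred == 0) & (t == 1)).sum())
    fp = int(((pred == 1) & (t == 0)).sum())
    tn = int(((pred == 0) & (t == 0)).sum())
    n1, n0 = tp + fn, fp + tn
    return ConfusionReport(
        tp_pct=100.0 * tp / n1 if n1 else float("nan"),
        fn_pct=100.0 * fn / n1 if n1 else float("nan"),
        fp_pct=100.0 * fp / n0 if n0 else float("nan"),
        tn_pct=100.0 * tn / n0 if n0 else float("nan"),
        threshold=threshold,
        counts={"tp": tp, "fn": fn, "fp": fp, "tn": tn},
    )


def _make_estimator(method: str, n_channels: int, C: float, seed: int):
    if method == "cbc":
        return CellBasedGraphClassifier(n_channels=n_channels, C=C, random_state=seed)
    if method == "mbc":
        return MatrixBasedGraphClassifier(n_channels=n_channels, C=C, random_state=seed)
    raise ValueError(f"unknown supervised method {method!r}")


def crossval_cell_scores(
    features: np.ndarray,
    labels: np.ndarray,
    method: str,
    n_channels: int,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Held-out cell scores from stratified k-fold cross-validation.

    Folds are stratified by graph index so every configuration appears in
    every training split whenever trials_per_graph >= folds.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n = features.shape[0]
    scores = np.full((n, n_channels, n_channels), np.nan)
    for train_idx, test_idx in skf.split(features, labels):
        est = _make_estimator(method, n_channels, C, seed)
        est.fit(features[train_idx], labels[train_idx])
        scores[test_idx] = est.predict_cell_scores(features[test_idx])
    return scores


def crossval_auc(
    dataset: LabeledDataset,
    method: str,
    mode: str = "complete",
    engineered: bool = True,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    threshold: float | None = None,
    features: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> ExperimentReport:
    """Cross-validated pooled AUC of one method on one dataset.

    Supervised methods ("cbc", "mbc") are trained on folds-1 folds and score
    the held-out fold; the held-out scores are pooled.  "gca" needs no
    training: scores are computed directly on every trial.  Precomputed
    ``features``/``labels`` may be passed to avoid re-featurising.
    """
    threshold = cost_threshold() if threshold is None else threshold
    truths = dataset.truth_tensor()
    if method == "gca":
        scores = gca_dataset_scores(dataset)
    else:
        if features is None or labels is None:
            features, labels, _ = featurize_dataset(
                dataset, mode=mode, engineered=engineered
            )
        scores = crossval_cell_scores(
            features, labels, method, dataset.M, folds=folds, seed=seed, C=C
        )
    roc = roc_auc(scores, truths)
    conf = confusion_at_threshold(scores, truths, threshold)
    return ExperimentReport(
        method=method,
        mode=mode if method != "gca" else "conditional",
        dataset=dataset.noise_mode,
        train_dataset=None,
        auc=roc.auc,
        roc=roc,
        confusion=conf,
        seed=seed,
        config={"folds": folds, "C": C, "engineered": engineered,
                "p": dataset.p, "N": dataset.N,
                "trials_per_graph": dataset.trials_per_graph},
        cell_scores=scores,
        truths=truths,
    )


def mismatch_auc(
    train_dataset: LabeledDataset,
    test_dataset: LabeledDataset,
    method: str = "cbc",
    mode: str = "complete",
    engineered: bool = True,
    seed: int = 0,
    C: float = 1.0,
    threshold: float | None = None,
    train_features=None,
    test_features=None,
) -> ExperimentReport:
    """Train once on one dataset, score every trial of another.

    Used for the generative-mismatch experiment (train on the noiseless
    dataset, test on the noisy one).
    """
    if (train_dataset.M, train_dataset.p) != (test_dataset.M, test_dataset.p):
        raise ValueError("train and test datasets must share M and p")
    threshold = cost_threshold() if threshold is None else threshold
    if train_features is None:
        train_features, train_labels, _ = featurize_dataset(
            train_dataset, mode=mode, engineered=engineered
        )
    else:
        train_features, train_labels = train_features
    if test_features is None:
        test_features, _, _ = featurize_dataset(
            test_dataset, mode=mode, engineered=engineered
        )
    est = _make_estimator(method, train_dataset.M, C, seed)
    est.fit(train_features, train_labels)
    scores = est.predict_cell_scores(test_features)
    truths = test_dataset.truth_tensor()
    roc = roc_auc(scores, truths)
    conf = confusion_at_threshold(scores, truths, threshold)
    return ExperimentReport(
        method=method,
        mode=mode,
        dataset=test_dataset.noise_mode,
        train_dataset=train_dataset.noise_mode,
        auc=roc.auc,
        roc=roc,
        confusion=conf,
        seed=seed,
        config={"C": C, "engineered": engineered, "p": train_dataset.p},
        cell_scores=scores,
        truths=truths,
    )


def replicate(
    table: str,
    trials_per_graph: int = 100,
    N: int = 1500,
    M: int = 3,
    p: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> list[ExperimentReport]:
    """End-to-end scaled replication of the benchmark experiments.

    "table3": GCA/CBC/MBC AUC on the noiseless and noisy datasets.
    "table4": CBC AUC with complete/c-pw/pw feature spaces on both datasets.
    "table5": confusion matrices of the three methods at the cost threshold.
    "mismatch": CBC trained noiseless, tested noisy.
    """
    if table not in ("table3", "table4", "table5", "mismatch"):
        raise ValueError(f"unknown replication target {table!r}")
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    clean = generate_dataset(M, p, N, trials_per_graph, "none", int(ss[0]))
    noisy = generate_dataset(M, p, N, trials_per_graph, "uniform", int(ss[1]))
    reports: list[ExperimentReport] = []
    if table == "table3":
        for ds in (clean, noisy):
            feats = featurize_dataset(ds, mode="complete", engineered=True)
            for method in ("gca", "cbc", "mbc"):
                reports.append(
                    crossval_auc(ds, method, folds=folds, seed=seed,
                                 features=feats[0], labels=feats[1])
                )
    elif table == "table4":
        for ds in (clean, noisy):
            for mode in ("complete", "c-pw", "pw"):
                reports.append(
                    crossval_auc(ds, "cbc", mode=mode, folds=folds, seed=seed)
                )
    elif table == "table5":
        feats = featurize_dataset(noisy, mode="complete", engineered=True)
        for method in ("gca", "cbc", "mbc"):
            reports.append(
                crossval_auc(noisy, method, folds=folds, seed=seed,
                             features=feats[0], labels=feats[1])
            )
    else:  # mismatch
        reports.append(
            mismatch_auc(clean, noisy, method="cbc", seed=seed)
        )
    return reports


def format_reports(reports: list[ExperimentReport]) -> str:
    lines = [f"{'method':8s} {'mode':12s} {'train':8s} {'test':8s} "
             f"{'AUC':>6s} {'FP%':>6s} {'TP%':>6s}"]
    for r in reports:
        lines.append(
            f"{r.method:8s} {r.mode:12s} "
            f"{(r.train_dataset or '-'):8s} {r.dataset:8s} "
            f"{r.auc:6.3f} {r.confusion.fp_pct:6.1f} {r.confusion.tp_pct:6.1f}"
        )
    return "\n".join(lines)
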