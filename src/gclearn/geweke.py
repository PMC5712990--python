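"""Conditional Geweke measure in the time domain (the unsupervised baseline).

For an ordered channel pair (i, j) the measure is

    F_{i->j} = ln( var(resid of x_j | lags of all channels except i)
                 / var(resid of x_j | lags of all channels) )

i.e. the log ratio of residual variances of the effect's lagged
autoregression with the candidate cause excluded vs included, conditioning
on every remaining channel.  Under the null of no Granger causality the
scaled statistic (N - p) * F is asymptotically chi-squared with p degrees of
freedom, which yields a per-cell p-value; the ROC score of a cell is
1 - p_value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import LabeledDataset, TrialRecord, offdiag_pairs
from .features import TrialScorer

__all__ = [
    "GewekeScores",
    "conditional_geweke",
    "gca_significance",
    "gca_score_matrix",
    "gca_scores",
    "gca_dataset_scores",
]


@dataclass(frozen=True)
class GewekeScores:
    """Per ordered pair (i, j): the measure, its p-value and the ROC score."""

    F_values: dict  # (i, j) -> log variance ratio (nats)
    p_values: dict  # (i, j) -> asymptotic p-value
    scores: dict  # (i, j) -> 1 - p_value

    def score_matrix(self, M: int) -> np.ndarray:
        out = np.full((M, M), np.nan)
        for (i, j), s in self.scores.items():
            out[i, j] = s
        return out


def _series(trial) -> np.ndarray:
    return trial.X if isinstance(trial, TrialRecord) else np.asarray(trial, float)


def conditional_geweke(trial, i: int, j: int, p: int,
                       scorer: TrialScorer | None = None) -> float:
    """F_{i->j}: conditional log residual-variance ratio at lag order p."""
    X = _series(trial)
    M = X.shape[1]
    if i == j:
        raise ValueError("cause and effect channels must differ")
    if not (0 <= i < M and 0 <= j < M):
        raise ValueError("channel index out of range")
    if scorer is None:
        scorer = TrialScorer(X, p)
    full = tuple(range(M))
    reduced = tuple(c for c in full if c != i)
    rv_red = scorer.residual_variance(reduced, j)
    rv_full = scorer.residual_variance(full, j)
    if rv_full <= 0.0:
        if rv_red <= 0.0:
            return 0.0  # both at the numerical floor: identical nested fits
        raise FloatingPointError(
            f"non-finite Geweke ratio for pair ({i},{j}): "
            f"rv_full={rv_full}, rv_reduced={rv_red}"
        )
    return float(np.log(rv_red / rv_full))


def gca_significance(F_value: float, N: int, p: int) -> float:
    """Asymptotic p-value of the null 'no Granger causality'.

    (N - p) * F ~ chi2(p) under the null; marginally negative F (numerical)
    is clamped to 0, giving p-value 1.
    """
    if not np.isfinite(F_value):
        raise ValueError("F value must be finite")
    if N <= p or p < 1:
        raise ValueError("need N > p >= 1")
    stat = max(float(F_value), 0.0) * (N - p)
    return float(stats.chi2.sf(stat, df=p))


def gca_scores(trial, p: int) -> GewekeScores:
    """Structured conditional-Geweke results for every ordered pair."""
    X = _series(trial)
    N, M = X.shape
    scorer = TrialScorer(X, p)
    F_values, p_values, scores = {}, {}, {}
    for (i, j) in offdiag_pairs(M):
        F = conditional_geweke(X, i, j, p, scorer=scorer)
        pv = gca_significance(F, N, p)
        F_values[(i, j)] = F
        p_values[(i, j)] = pv
        scores[(i, j)] = 1.0 - pv
    return GewekeScores(F_values=F_values, p_values=p_values, scores=scores)


def gca_score_matrix(trial, p: int) -> np.ndarray:
    """(M, M) matrix of per-cell scores 1 - p_value; diagonal is NaN."""
    M = _series(trial).shape[1]
    return gca_scores(trial, p).score_matrix(M)


def gca_dataset_scores(dataset: LabeledDataset, p: int | None = None) -> np.ndarray:
    """Stack of per-trial score matrices, (n_trials, M, M)."""
    p = dataset.p if p is None else p
    return np.stack([gca_score_matrix(tr, p) for tr in dataset.trials])
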