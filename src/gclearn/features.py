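"""Causality-scenario feature space.

A *causality scenario* is a pair (cause subset, effect channel).  Each
scenario defines one lagged least-squares problem: predict x_effect(t) from
the p previous samples of every cause channel, for every admissible t in
{p, ..., N-1}.  Scoring all (2^M - 1) * M scenarios of a trial with the mean
squared error and the coefficient of determination, plus the M(M-1)
conditional Geweke log variance ratios assembled from the same fits, yields
the trial's feature vector.  Optional feature engineering appends elementwise
powers, signed square roots and all pairwise products.

Two reduced scenario families mirror classic bivariate Granger testing:
``pw`` keeps, per effect j, the scenarios {j}->j and {i,j}->j; ``c-pw``
keeps the full-set scenario and its leave-one-out versions.  Both have M^2
members.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .simulate import LabeledDataset, TrialRecord, offdiag_pairs

__all__ = [
    "CausalityScenario",
    "RegressionProblem",
    "FeatureVector",
    "enumerate_scenarios",
    "reduce_scenarios",
    "build_lagged_problem",
    "fit_and_score",
    "lagged_design",
    "TrialScorer",
    "compute_features",
    "engineer_features",
    "featurize_dataset",
    "ScenarioFeaturizer",
]

_EPS_VAR = 1e-12  # below this total variance a target counts as constant


@dataclass(frozen=True)
class CausalityScenario:
    """(cause subset, effect) pair; causes are stored sorted."""

    causes: tuple[int, ...]
    effect: int

    def __post_init__(self):
        if len(self.causes) == 0:
            raise ValueError("cause set must be non-empty")
        object.__setattr__(self, "causes", tuple(sorted(set(self.causes))))

    @property
    def name(self) -> str:
        c = ",".join(str(i) for i in self.causes)
        return f"{{{c}}}->{self.effect}"


def enumerate_scenarios(M: int) -> list[CausalityScenario]:
    """All (2^M - 1) * M scenarios, effect-major, subsets by size then lex."""
    if M <= 0:
        raise ValueError(f"channel count must be positive, got {M}")
    subsets = [
        combo
        for size in range(1, M + 1)
        for combo in itertools.combinations(range(M), size)
    ]
    return [
        CausalityScenario(causes=s, effect=j) for j in range(M) for s in subsets
    ]


def reduce_scenarios(
    scenarios: list[CausalityScenario], mode: str, M: int
) -> list[CausalityScenario]:
    """Restrict the scenario family to the pairwise / conditional families."""
    if mode == "complete":
        return list(scenarios)
    available = set(scenarios)
    out: list[CausalityScenario] = []
    if mode == "pw":
        for j in range(M):
            out.append(CausalityScenario((j,), j))
            for i in range(M):
                if i != j:
                    out.append(CausalityScenario((i, j), j))
    elif mode == "c-pw":
        full = tuple(range(M))
        for j in range(M):
            out.append(CausalityScenario(full, j))
            for i in range(M):
                if i != j:
                    out.append(
                        CausalityScenario(tuple(c for c in full if c != i), j)
                    )
    else:
        raise ValueError(f"unknown scenario mode {mode!r}")
    missing = [s for s in out if s not in available]
    if missing:
        raise ValueError(f"reduced scenarios not in the provided family: {missing}")
    # M = 2 duplicates ({i,j}->j coincides with the leave-one-out set); keep
    # first occurrence only
    seen: set[CausalityScenario] = set()
    uniq = [s for s in out if not (s in seen or seen.add(s))]
    return uniq


@dataclass
class RegressionProblem:
    """Design/target pair of one scenario's lagged regression."""

    design: np.ndarray  # (N - p, p * |causes|)
    targets: np.ndarray  # (N - p,)
    scenario: CausalityScenario
    p: int


def lagged_design(X: np.ndarray, p: int, channels=None) -> np.ndarray:
    """Lagged design matrix: row t-p holds [x_c(t-p), ..., x_c(t-1)] per channel.

    Channels are laid out in ascending order, each contributing p consecutive
    columns (oldest lag first).  Row for time t contains no value at time >= t.
    """
    X = np.asarray(X, dtype=float)
    N, M = X.shape
    if N <= p:
        raise ValueError(f"need N > p, got N={N}, p={p}")
    if channels is None:
        channels = range(M)
    n = N - p
    cols = []
    for c in channels:
        block = np.empty((n, p))
        for k in range(p):
            block[:, k] = X[k : k + n, c]
        cols.append(block)
    return np.hstack(cols)


def build_lagged_problem(
    trial: TrialRecord | np.ndarray, scenario: CausalityScenario, p: int
) -> RegressionProblem:
    X = trial.X if isinstance(trial, TrialRecord) else np.asarray(trial, float)
    design = lagged_design(X, p, channels=scenario.causes)
    targets = X[p:, scenario.effect].copy()
    return RegressionProblem(design=design, targets=targets, scenario=scenario, p=p)


def fit_and_score(problem: RegressionProblem) -> tuple[float, float, float]:
    """OLS with intercept; returns (mse, r2, unbiased residual variance).

    Uses a rank-tolerant solver (minimum-norm solution on rank deficiency).
    A constant target yields r2 = 0 by convention.
    """
    Z = np.asarray(problem.design, dtype=float)
    y = np.asarray(problem.targets, dtype=float)
    n = Z.shape[0]
    if n < 1:
        raise ValueError("regression problem has no rows")
    D = np.hstack([Z, np.ones((n, 1))])
    coef, _, _, _ = scipy.linalg.lstsq(D, y, lapack_driver="gelsd")
    resid = y - D @ coef
    ssres = float(resid @ resid)
    sstot = float(((y - y.mean()) ** 2).sum())
    mse = ssres / n
    r2 = 1.0 - ssres / sstot if sstot > _EPS_VAR else 0.0
    rv = ssres / max(n - D.shape[1], 1)
    return mse, r2, rv


class TrialScorer:
    """Scores every scenario of one trial from a single gram matrix.

    The full lagged design (all channels, plus intercept) is formed once;
    each scenario's normal equations are then a principal submatrix solve.
    Solutions use a rank-tolerant pseudo-inverse path, matching the
    minimum-norm OLS solution on the raw design.
    """

    def __init__(self, X: np.ndarray, p: int):
        X = np.asarray(X, dtype=float)
        self.N, self.M = X.shape
        self.p = p
        Z = lagged_design(X, p)
        self.n = Z.shape[0]
        D = np.hstack([Z, np.ones((self.n, 1))])
        self._icol = self.M * p  # intercept column
        self.G = D.T @ D
        self.Y = X[p:, :]
        self.B = D.T @ self.Y
        self.yty = np.einsum("ij,ij->j", self.Y, self.Y)
        self.ybar = self.Y.mean(axis=0)
        self._cache: dict[tuple[tuple[int, ...], int], tuple[float, float, float]] = {}

    def target_is_constant(self, effect: int) -> bool:
        sstot = float(self.yty[effect] - self.n * self.ybar[effect] ** 2)
        return sstot <= _EPS_VAR

    def _cols(self, causes: tuple[int, ...]) -> list[int]:
        return [c * self.p + k for c in causes for k in range(self.p)] + [self._icol]

    def score(self, scenario: CausalityScenario) -> tuple[float, float, float]:
        key = (scenario.causes, scenario.effect)
        if key in self._cache:
            return self._cache[key]
        idx = self._cols(scenario.causes)
        Gs = self.G[np.ix_(idx, idx)]
        bs = self.B[idx, scenario.effect]
        coef, _, _, _ = np.linalg.lstsq(Gs, bs, rcond=None)
        ssres = float(self.yty[scenario.effect] - 2.0 * coef @ bs + coef @ Gs @ coef)
        ssres = max(ssres, 0.0)
        sstot = float(
            self.yty[scenario.effect] - self.n * self.ybar[scenario.effect] ** 2
        )
        mse = ssres / self.n
        r2 = 1.0 - ssres / sstot if sstot > _EPS_VAR else 0.0
        rv = ssres / max(self.n - len(idx), 1)
        out = (mse, r2, rv)
        self._cache[key] = out
        return out

    def residual_variance(self, causes: tuple[int, ...], effect: int) -> float:
        """ML residual variance (SSres / n).

        Geweke log ratios must compare nested fits under a *common*
        normalisation, otherwise identical fits with different regressor
        counts would yield a spurious non-zero measure; the unbiased
        variance (differing dof) is therefore not used here.
        """
        return self.score(CausalityScenario(tuple(causes), effect))[0]


@dataclass
class FeatureVector:
    """Scenario scores (and optional engineered expansion) of one trial."""

    base: np.ndarray  # (2 * n_scenarios,): mse, r2 per scenario
    geweke: np.ndarray  # (M(M-1),): conditional log variance ratios
    names: list[str]
    engineered: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        parts = [self.base, self.geweke]
        if self.engineered is not None:
            parts.append(self.engineered)
        return np.concatenate(parts)


def _geweke_pairs_for_mode(mode: str, M: int) -> list[tuple]:
    """(pair, reduced causes, full causes) per ordered (cause, effect) pair."""
    full = tuple(range(M))
    out = []
    for (i, j) in offdiag_pairs(M):
        if mode == "pw":
            out.append(((i, j), (j,), tuple(sorted((i, j)))))
        else:  # complete and c-pw share the conditional construction
            out.append(((i, j), tuple(c for c in full if c != i), full))
    return out


def compute_features(
    trial: TrialRecord | np.ndarray, p: int, mode: str = "complete"
) -> FeatureVector:
    """Score every scenario of the selected family on one trial.

    The base block is (mse, r2) per scenario in canonical order; the Geweke
    block holds, per ordered pair (i, j), the log ratio of residual variances
    of the effect's model without vs with the candidate cause's lags
    (conditional on all remaining channels in complete/c-pw modes, bivariate
    in pw mode).  All ratios reuse already-fitted scenarios.
    """
    X = trial.X if isinstance(trial, TrialRecord) else np.asarray(trial, float)
    M = X.shape[1]
    scenarios = reduce_scenarios(enumerate_scenarios(M), mode, M)
    scorer = TrialScorer(X, p)
    base = np.empty(2 * len(scenarios))
    names: list[str] = []
    constant = [j for j in range(M) if scorer.target_is_constant(j)]
    flags = {"constant_targets": constant} if constant else {}
    for s_i, sc in enumerate(scenarios):
        mse, r2, _ = scorer.score(sc)
        base[2 * s_i] = mse
        base[2 * s_i + 1] = r2
        names += [f"mse[{sc.name}]", f"r2[{sc.name}]"]
    gpairs = _geweke_pairs_for_mode(mode, M)
    geweke = np.empty(len(gpairs))
    for k, (pair, reduced, fullset) in enumerate(gpairs):
        rv_red = scorer.residual_variance(reduced, pair[1])
        rv_full = scorer.residual_variance(fullset, pair[1])
        geweke[k] = _safe_log_ratio(rv_red, rv_full)
        names.append(f"gc[{pair[0]}->{pair[1]}]")
    return FeatureVector(base=base, geweke=geweke, names=names, meta=flags)


def _safe_log_ratio(rv_red: float, rv_full: float) -> float:
    if rv_full <= 0.0:
        # both residual variances at the numerical floor: no evidence either way
        return 0.0 if rv_red <= 0.0 else np.inf
    return float(np.log(rv_red / rv_full))


# ---------------------------------------------------------------------------
# feature engineering


def _engineer_matrix(raw: np.ndarray, names: list[str]):
    """Vectorised expansion: powers, signed sqrt, pairwise products."""
    R = raw.shape[1]
    iu, ju = np.triu_indices(R, k=1)
    blocks = [
        raw**2,
        raw**3,
        np.sign(raw) * np.sqrt(np.abs(raw)),
        raw[:, iu] * raw[:, ju],
    ]
    new_names = (
        [f"({n})^2" for n in names]
        + [f"({n})^3" for n in names]
        + [f"ssqrt({n})" for n in names]
        + [f"({names[i]})*({names[j]})" for i, j in zip(iu, ju)]
    )
    return np.hstack(blocks), new_names


def engineer_features(v: FeatureVector) -> FeatureVector:
    """Append x^2, x^3, sign(x)*sqrt(|x|) and all pairwise products."""
    raw = np.concatenate([v.base, v.geweke])[None, :]
    eng, new_names = _engineer_matrix(raw, v.names)
    return FeatureVector(
        base=v.base,
        geweke=v.geweke,
        names=v.names + new_names,
        engineered=eng[0],
        meta=dict(v.meta),
    )


def n_features(M: int, mode: str = "complete", engineered: bool = True) -> int:
    n_scen = len(reduce_scenarios(enumerate_scenarios(M), mode, M))
    R = 2 * n_scen + M * (M - 1)
    return R * 4 + R * (R - 1) // 2 if engineered else R


def featurize_dataset(
    dataset: LabeledDataset,
    p: int | None = None,
    mode: str = "complete",
    engineered: bool = True,
):
    """Feature matrix, per-trial graph-index labels and feature names."""
    p = dataset.p if p is None else p
    rows = []
    names: list[str] | None = None
    for tr in dataset.trials:
        fv = compute_features(tr, p, mode)
        rows.append(np.concatenate([fv.base, fv.geweke]))
        if names is None:
            names = fv.names
    raw = np.vstack(rows)
    assert names is not None
    if engineered:
        eng, new_names = _engineer_matrix(raw, names)
        raw = np.hstack([raw, eng])
        names = names + new_names
    labels = dataset.graph_indices()
    return raw, labels, names


class ScenarioFeaturizer:
    """Stateless sklearn-style transformer from raw trials to features.

    ``transform`` accepts a LabeledDataset or a sequence of (N, M) arrays and
    returns the feature matrix.  ``fit`` is a no-op kept for pipeline
    compatibility.
    """

    def __init__(self, p: int = 10, mode: str = "complete", engineered: bool = True):
        self.p = p
        self.mode = mode
        self.engineered = engineered

    def get_params(self, deep: bool = True):
        return {"p": self.p, "mode": self.mode, "engineered": self.engineered}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("p", "mode", "engineered"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        if isinstance(X, LabeledDataset):
            mat, _, self.feature_names_ = featurize_dataset(
                X, self.p, self.mode, self.engineered
            )
            return mat
        rows = []
        names = None
        for series in X:
            fv = compute_features(np.asarray(series, float), self.p, self.mode)
            rows.append(np.concatenate([fv.base, fv.geweke]))
            names = fv.names
        raw = np.vstack(rows)
        if self.engineered:
            eng, new_names = _engineer_matrix(raw, names)
            raw = np.hstack([raw, eng])
            names = names + new_names
        self.feature_names_ = names
        return raw

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
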