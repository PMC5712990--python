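"""Labeled multivariate-autoregressive (MAR) trial generation.

The generative model produces a trial ``X = (1 - gamma) * X_s + gamma * X_n``
where both components follow a MAR(p) recursion

    X(t) = sum_{tau=1..p} A(tau)^T X(t - tau) + eps(t),   eps ~ N(0, I_M)

``X_s`` carries the causal structure: its coefficient matrices share the zero
pattern of a binary M x M *causal configuration matrix* A, whose entry (i, j)
declares a lagged influence of channel i on channel j.  ``X_n`` is an
independent noise component with diagonal (channel-wise) coefficients, and
``gamma`` in [0, 1] tunes the signal-to-noise ratio.

Datasets enumerate all 2^(M(M-1)) off-diagonal configurations and contain the
same number of trials per configuration, so a classifier trained on them sees
the whole population of causal graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CausalGraph",
    "MARParameters",
    "TrialRecord",
    "LabeledDataset",
    "offdiag_pairs",
    "enumerate_graphs",
    "graph_to_index",
    "index_to_graph",
    "companion_matrix",
    "spectral_radius",
    "is_stationary",
    "sample_signal_coeffs",
    "sample_noise_coeffs",
    "simulate_component",
    "mix",
    "generate_dataset",
]

#: default cap on the total number of trials a single call may generate
MAX_TRIALS = 1_000_000

#: shrinkage target for the companion spectral radius when a raw coefficient
#: draw is non-stationary
_SHRINK_TARGET = 0.95


def offdiag_pairs(M: int) -> list[tuple[int, int]]:
    """Ordered (cause, effect) pairs: off-diagonal cells read row-major.

    This single ordering defines the bit layout of the graph index, the cell
    order of cell-based classifiers and the layout of Geweke feature blocks.
    """
    return [(i, j) for i in range(M) for j in range(M) if i != j]


@dataclass(frozen=True)
class CausalGraph:
    """Binary M x M causal configuration matrix.

    ``entries[i, j] == 1`` means channel i exerts a lagged influence on
    channel j.  The diagonal is fixed to 1 (every channel has its own
    autoregressive dynamics); the M(M-1) off-diagonal cells are the free
    parameters and the classification label.
    """

    entries: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.entries, dtype=int)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("causal graph must be a square matrix")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("causal graph entries must be 0 or 1")
        if not (np.diag(a) == 1).all():
            raise ValueError("causal graph diagonal is fixed to 1")
        a.setflags(write=False)
        object.__setattr__(self, "entries", a)

    @property
    def M(self) -> int:
        return self.entries.shape[0]

    @property
    def index(self) -> int:
        return graph_to_index(self)

    def __eq__(self, other):
        return isinstance(other, CausalGraph) and np.array_equal(
            self.entries, other.entries
        )

    def __hash__(self):
        return hash((self.M, graph_to_index(self)))

    def __repr__(self):
        return f"CausalGraph(M={self.M}, index={graph_to_index(self)})"


def enumerate_graphs(M: int) -> list[CausalGraph]:
    """All 2^(M(M-1)) causal graphs in canonical (index) order."""
    if M <= 0:
        raise ValueError(f"channel count must be positive, got {M}")
    return [index_to_graph(k, M) for k in range(2 ** (M * (M - 1)))]


def graph_to_index(graph: CausalGraph) -> int:
    """Canonical integer index: off-diagonal cells row-major, LSB first."""
    bits = [graph.entries[i, j] for (i, j) in offdiag_pairs(graph.M)]
    return int(sum(b << k for k, b in enumerate(bits)))


def index_to_graph(index: int, M: int) -> CausalGraph:
    n_free = M * (M - 1)
    if not 0 <= index < 2**n_free:
        raise ValueError(f"graph index {index} out of range for M={M}")
    a = np.eye(M, dtype=int)
    for k, (i, j) in enumerate(offdiag_pairs(M)):
        a[i, j] = (index >> k) & 1
    return CausalGraph(a)


# ---------------------------------------------------------------------------
# stationarity


def _as_coeff_tensor(coeffs) -> np.ndarray:
    c = np.asarray(coeffs, dtype=float)
    if c.ndim != 3 or c.shape[1] != c.shape[2]:
        raise ValueError(
            "coefficients must be a p-sequence of square M x M matrices"
        )
    return c


def companion_matrix(coeffs) -> np.ndarray:
    """(Mp) x (Mp) companion matrix of the MAR(p) recursion."""
    c = _as_coeff_tensor(coeffs)
    p, M, _ = c.shape
    top = np.hstack([c[tau].T for tau in range(p)])
    comp = np.zeros((M * p, M * p))
    comp[:M] = top
    if p > 1:
        comp[M:, : M * (p - 1)] = np.eye(M * (p - 1))
    return comp


def spectral_radius(coeffs) -> float:
    return float(np.abs(np.linalg.eigvals(companion_matrix(coeffs))).max())


def is_stationary(coeffs) -> bool:
    """True iff the companion-matrix spectral radius is < 1."""
    return spectral_radius(coeffs) < 1.0


def _shrink_to_stationary(coeffs: np.ndarray) -> np.ndarray:
    """Rescale a coefficient tensor until the MAR(p) system is stationary.

    A uniform rescaling does not move the companion eigenvalues linearly, so
    the factor 0.95/rho is applied repeatedly; each pass strictly shrinks the
    tensor (rho >= 1 implies factor <= 0.95), so the loop terminates.
    """
    rho = spectral_radius(coeffs)
    while rho >= 1.0:
        coeffs = coeffs * (_SHRINK_TARGET / rho)
        rho = spectral_radius(coeffs)
    return coeffs


# ---------------------------------------------------------------------------
# coefficient sampling


def sample_signal_coeffs(
    graph: CausalGraph, p: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw signal coefficients A_s(tau), tau=1..p, masked by the graph.

    Masked entries (including the diagonal) are standard-uniform draws on
    (0, 1) — positive couplings, the plain reading of "uniformly distributed
    random numbers" — and the tensor is then rescaled if needed so the MAR(p)
    system is stationary.  Entries where the graph is 0 are exactly 0 at
    every lag.
    """
    if p < 1:
        raise ValueError(f"lag order must be positive, got {p}")
    draws = rng.uniform(0.0, 1.0, size=(p, graph.M, graph.M))
    coeffs = draws * graph.entries[None, :, :]
    return _shrink_to_stationary(coeffs)


def sample_noise_coeffs(M: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """Draw p diagonal M x M noise coefficient matrices A_n(tau).

    Diagonality makes the noise component M independent univariate AR(p)
    processes.  Entries are standard-uniform draws, rescaled to stationarity.
    """
    if M < 1 or p < 1:
        raise ValueError("M and p must be positive")
    diag = rng.uniform(0.0, 1.0, size=(p, M))
    coeffs = np.zeros((p, M, M))
    for tau in range(p):
        np.fill_diagonal(coeffs[tau], diag[tau])
    return _shrink_to_stationary(coeffs)


@dataclass(frozen=True)
class MARParameters:
    """Full parameter set of one trial's generative model."""

    order: int
    signal_coeffs: np.ndarray  # (p, M, M)
    noise_coeffs: np.ndarray  # (p, M, M), diagonal
    gamma: float

    def __post_init__(self):
        sc = _as_coeff_tensor(self.signal_coeffs)
        nc = _as_coeff_tensor(self.noise_coeffs)
        if sc.shape != nc.shape or sc.shape[0] != self.order:
            raise ValueError("coefficient tensors inconsistent with order")
        off = ~np.eye(sc.shape[1], dtype=bool)
        if np.any(nc[:, off] != 0.0):
            raise ValueError("noise coefficients must be diagonal")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not (is_stationary(sc) and is_stationary(nc)):
            raise ValueError("coefficient tensors must be stationary")


# ---------------------------------------------------------------------------
# simulation


def _simulate_batch(coeffs: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Run the MAR(p) recursion for a batch of trials.

    coeffs: (B, p, M, M), eps: (B, T, M).  Initial state is zero.  Returns
    (B, T, M).  Each trial in the batch is numerically independent, so a
    batch of one reproduces the single-trial path bit for bit.
    """
    B, p, M, _ = coeffs.shape
    T = eps.shape[1]
    # rev[:, k] = A(tau = p - k): aligns with the sliding window so that
    # window position k holds X(t - (p - k))
    rev = coeffs[:, ::-1]
    X = np.zeros((B, T + p, M))
    for t in range(p, T + p):
        X[:, t] = (
            np.einsum("bkij,bki->bj", rev, X[:, t - p : t]) + eps[:, t - p]
        )
    return X[:, p:]


def simulate_component(
    coeffs, N: int, burn_in: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one MAR(p) component of length N (after burn-in).

    Innovations are i.i.d. M-dimensional standard normal; the first
    ``burn_in`` samples are discarded to remove the zero-initialisation
    transient.
    """
    c = _as_coeff_tensor(coeffs)
    p, M, _ = c.shape
    if N <= p:
        raise ValueError(f"series length N={N} must exceed the lag order p={p}")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    if not is_stationary(c):
        raise ValueError("refusing to simulate a non-stationary MAR system")
    eps = rng.standard_normal((N + burn_in, M))
    out = _simulate_batch(c[None], eps[None])[0]
    return out[burn_in:]


def mix(X_s: np.ndarray, X_n: np.ndarray, gamma: float) -> np.ndarray:
    """Convex combination (1 - gamma) * X_s + gamma * X_n."""
    X_s = np.asarray(X_s, dtype=float)
    X_n = np.asarray(X_n, dtype=float)
    if X_s.shape != X_n.shape:
        raise ValueError("signal and noise components must share a shape")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return (1.0 - gamma) * X_s + gamma * X_n


# ---------------------------------------------------------------------------
# datasets


@dataclass
class TrialRecord:
    """One simulated (or observed) multichannel series with its label."""

    X: np.ndarray  # (N, M)
    graph: CausalGraph | None
    gamma: float
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("trial series must be a 2-D (N x M) array")
        if not np.isfinite(self.X).all():
            raise ValueError("trial series contains non-finite values")


@dataclass
class LabeledDataset:
    """Balanced collection of trials covering every causal configuration."""

    trials: list[TrialRecord]
    M: int
    p: int
    N: int
    trials_per_graph: int
    noise_mode: str = "none"
    seed: int = 0

    def __len__(self):
        return len(self.trials)

    def graph_indices(self) -> np.ndarray:
        return np.array([graph_to_index(t.graph) for t in self.trials])

    def truth_tensor(self) -> np.ndarray:
        """(n_trials, M, M) stack of ground-truth configuration matrices."""
        return np.stack([t.graph.entries for t in self.trials]).astype(float)

    def series(self) -> list[np.ndarray]:
        return [t.X for t in self.trials]


def default_burn_in(p: int) -> int:
    return max(500, 10 * p)


def _trial_rng(seed: int, graph_index: int, replicate: int) -> np.random.Generator:
    """Per-trial stream derived deterministically from (seed, graph, replicate)."""
    ss = np.random.SeedSequence([int(seed), int(graph_index), int(replicate)])
    return np.random.default_rng(ss)


def generate_dataset(
    M: int,
    p: int,
    N: int,
    trials_per_graph: int,
    noise_mode: str = "none",
    seed: int = 0,
    burn_in: int | None = None,
    batch_size: int = 256,
    force: bool = False,
) -> LabeledDataset:
    """Generate a balanced labeled MAR dataset.

    ``noise_mode="none"`` keeps gamma = 0 on every trial (pure causal
    component); ``"uniform"`` draws gamma ~ Uniform[0, 1] per trial.  Every
    trial gets fresh signal/noise coefficients and innovations from its own
    deterministic stream, so the dataset is reproducible from ``seed`` alone
    and independent of batching.
    """
    if min(M, p, trials_per_graph) < 1 or N <= p:
        raise ValueError("M, p, trials_per_graph must be positive and N > p")
    if noise_mode not in ("none", "uniform"):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    graphs = enumerate_graphs(M)
    total = len(graphs) * trials_per_graph
    if total > MAX_TRIALS and not force:
        raise ValueError(
            f"{total} trials exceeds the safety cap {MAX_TRIALS}; "
            "pass force=True to override"
        )
    if burn_in is None:
        burn_in = default_burn_in(p)
    T = N + burn_in

    # draw per-trial parameters and innovations from per-trial streams,
    # then run the recursion in batches for speed
    pending: list[tuple[int, int, np.ndarray, np.ndarray, float,
                        np.ndarray, np.ndarray]] = []
    trials: list[TrialRecord] = [None] * total  # type: ignore[list-item]

    def flush():
        if not pending:
            return
        As = np.stack([row[2] for row in pending])
        An = np.stack([row[3] for row in pending])
        Es = np.stack([row[5] for row in pending])
        En = np.stack([row[6] for row in pending])
        Xs = _simulate_batch(As, Es)[:, burn_in:]
        Xn = _simulate_batch(An, En)[:, burn_in:]
        for b, (gi, rep, _, _, gamma, _, _) in enumerate(pending):
            X = mix(Xs[b], Xn[b], gamma)
            trials[gi * trials_per_graph + rep] = TrialRecord(
                X=X,
                graph=graphs[gi],
                gamma=gamma,
                seed=seed,
                meta={"graph_index": gi, "replicate": rep},
            )
        pending.clear()

    for gi, graph in enumerate(graphs):
        for rep in range(trials_per_graph):
            rng = _trial_rng(seed, gi, rep)
            A_s = sample_signal_coeffs(graph, p, rng)
            A_n = sample_noise_coeffs(M, p, rng)
            gamma = float(rng.uniform()) if noise_mode == "uniform" else 0.0
            eps_s = rng.standard_normal((T, M))
            eps_n = rng.standard_normal((T, M))
            pending.append((gi, rep, A_s, A_n, gamma, eps_s, eps_n))
            if len(pending) >= batch_size:
                flush()
    flush()

    return LabeledDataset(
        trials=trials,
        M=M,
        p=p,
        N=N,
        trials_per_graph=trials_per_graph,
        noise_mode=noise_mode,
        seed=seed,
    )
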