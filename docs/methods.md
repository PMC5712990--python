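# Methods

## The problem

Granger-style causal inference asks whether the past of one time series
improves prediction of another beyond the target's own past. The classical
parametric answer — the conditional Geweke measure in the time domain,
thresholded by an asymptotic significance test — is known to be fragile when
the observed signals are corrupted by additive autocorrelated noise, as they
are in electrophysiology. `gclearn` implements the supervised alternative:
treat causal-graph recovery as a classification problem, generate labeled
trials from the assumed generative model, represent each trial in a feature
space built from the same precedence-and-predictability principle, and train
classifiers to predict the graph. The package also implements the classical
baseline so that both approaches can be compared on identical data.

## Generative model

A trial is `X = (1 − γ)·X_s + γ·X_n`, where both components follow a
vector-autoregressive recursion of order `p`

    X(t) = Σ_{τ=1..p} A(τ)^⊤ X(t−τ) + ε(t),   ε(t) ~ N(0, I_M),

and γ ∈ [0, 1] sets the noise share. The signal component's coefficient
matrices `A_s(τ)` inherit the zero pattern of a binary M×M causal
configuration matrix `A` (entry `(i, j) = 1` ⇔ channel *i* drives channel
*j*); the noise component's `A_n(τ)` are diagonal, so its channels are
independent univariate AR(p) processes. Note that a convex mixture of two
AR(p) processes is **not** an AR(p) process (it is ARMA), which is precisely
the misspecification that degrades the Geweke test on noisy data.

Model choices that the underlying description leaves open, resolved here:

* **Coefficient distribution.** Non-zero entries of `A_s(τ)` and the
  diagonals of `A_n(τ)` are standard-uniform draws on (0, 1) — i.e.
  positive couplings, the plain "uniformly distributed random numbers" of
  the MATLAB/NumPy `rand` convention. Positive couplings matter: signed
  draws partially cancel across lags, weakening the cross-correlation
  structure and with it the noise-induced failure mode of the Geweke test
  that the benchmark is designed to exhibit.
* **Stationarity enforcement.** If a drawn tensor fails the companion-matrix
  spectral-radius test, the whole tensor is rescaled by `0.95/ρ` and
  re-checked until stationary. The loop always terminates (each pass shrinks
  the tensor by at least 0.95) and leaves systems close to the stationarity
  boundary, i.e. strongly autocorrelated — the hard regime.
* **Diagonal of A.** Self-connections are fixed to 1 so every channel has
  its own autoregressive dynamics; without them the effect-only scenarios
  (`{j} → j`) would regress on white noise and be degenerate.
* **Burn-in.** `max(500, 10·p)` samples from a zero initial state are
  discarded.
* **γ for the noisy dataset.** One Uniform[0, 1] draw per trial.
* **Randomness.** Every trial has its own deterministic stream derived from
  `(master seed, graph index, replicate index)`, so datasets are bit-for-bit
  reproducible and independent of simulation batching.

Datasets enumerate all `2^{M(M−1)}` configurations (64 for M = 3) with an
equal number of trials per configuration. A safety cap refuses more than
10⁶ trials unless explicitly overridden.

## Feature space

For each of the `(2^M − 1)·M` causality scenarios (cause subset → effect) a
lagged regression problem is assembled: for every `t ∈ {p, …, N−1}` the row
concatenates `[x_c(t−p), …, x_c(t−1)]` over the cause channels and the
target is `x_effect(t)`. All admissible time points are used (no
subsampling), the fit is in-sample ordinary least squares with intercept,
and rank deficiency falls back to the minimum-norm solution. Each scenario
contributes its mean squared error and coefficient of determination r²
(42 values for M = 3). A Geweke block adds, for each ordered pair `(i, j)`,
the conditional log variance ratio `ln(rv[all∖{i} → j] / rv[all → j])`
computed from the already-fitted scenarios — the "estimate of the Granger
causality coefficients" of the original pipeline, taken here as the
canonical per-pair Granger scalar. Ratios use the ML residual variance
(SSres/n): nested in-sample fits then guarantee a non-negative measure,
which an unbiased-variance ratio (different degrees of freedom in numerator
and denominator) would not.

Feature engineering appends `x²`, `x³`, `sign(x)·√|x|` and all unordered
pairwise products of the raw features: 48 raw features become 1320 for
M = 3. The signed square root extends the transform to the marginally
negative values numerical Geweke ratios can take; products are taken over
raw features only, keeping growth quadratic.

The reduced families mirror classical testing: `pw` keeps `{j} → j` and
`{i, j} → j` per effect (bivariate Geweke), `c-pw` keeps the full-set
scenario and its leave-one-out versions (conditional Geweke); both have M²
members. In `pw` mode the Geweke block uses the bivariate ratio
`ln(rv[{j} → j]/rv[{i,j} → j])`.

For speed, all scenarios of one trial are scored from a single gram matrix
of the full lagged design (principal-submatrix normal equations); tests
verify agreement with direct least squares on the raw design to 1e-8.

## Classifiers

Both schemes consume the identical feature matrix, standardised with
training-fold statistics (the engineered features span orders of magnitude
and L2-penalised linear models are scale-sensitive).

* **CBC** (cell-based): M(M−1) independent binary L2-regularised logistic
  regressions, one per off-diagonal cell; the cell score is the posterior
  P(cell = 1). A training cell with a single class degenerates to a
  constant predictor with a warning.
* **MBC** (matrix-based): one multinomial L2 logistic regression over all
  `2^{M(M−1)}` configurations; the cell score is the marginal posterior mass
  of configurations whose cell is 1, so all cells of a trial are jointly
  thresholded through a single posterior.

Regularisation defaults to C = 1.0 (inverse strength) with no inner model
selection; the solver is deterministic L-BFGS with tolerance 1e-4 and a cap
of 1000 iterations. Graph prediction thresholds the cell scores; under the
benchmark's asymmetric cost model (+1 for a true positive, −3 for a false
positive) the break-even threshold is `3/(1+3) = 0.75` — an edge is only
worth predicting when its posterior clears the penalty ratio, which biases
predictions toward few false positives.

## Geweke baseline (GCA)

The conditional Geweke measure is implemented from scratch on the same OLS
machinery: `F_{i→j} = ln(rv_reduced/rv_full)` with the reduced model
excluding channel *i*'s lags and both models conditioning on all remaining
channels, at the generating lag order (no order selection, removing that
confound from the comparison). Significance uses the large-sample result
`(N − p)·F ~ χ²_p` under the null; the ROC score of a cell is `1 − p`.
Negative-by-rounding F values are clamped to zero for the test statistic.
No multiple-comparison correction is applied: the ROC sweeps the threshold,
and the fixed-threshold confusion matrices use the raw per-cell rule.

## Evaluation

All off-diagonal (cell, trial) decisions are pooled into one binary scoring
problem (micro-averaging, matching the "averaging over all cells and all
trials" construction); the AUC is trapezoidal over the threshold sweep, with
ties handled by the standard half-credit convention (verified against an
exhaustive pair-counting oracle). Cross-validation is stratified by graph
index with a fixed seed so every configuration appears in every training
split whenever trials per graph ≥ folds. Confusion matrices are
row-normalised percentages at the cost threshold.

## Problem sizes

The reference experiments used N = 6000 and 1000 trials per configuration
(64 000 trials per dataset). The package's replication scripts and
acceptance run use N = 1500 and 100 trials per configuration (6400 trials),
which keeps pooled-AUC estimates stable to roughly ±0.02–0.03 across seeds;
the unit-test suite uses still smaller instances (M = 2, short series)
chosen so that the asserted properties hold with margin. The absolute AUC
of the Geweke baseline drifts upward a few points as N shrinks (the
misspecification statistic scales with N), which is visible when comparing
desk-scale numbers with the reference ones.

## Known limitations

* The generator is linear and Gaussian with diagonal noise coupling; no
  non-linear or spectral variants, and no mixed noise covariance.
* Passing benchmarks on simulated trials shows the supervised pipeline
  dominates the Geweke baseline *under this generative family and its
  mismatch variant*; it says nothing about non-autoregressive real
  recordings, where only the relative robustness argument carries over.
* The feature space grows as `(2^M − 1)·M` scenarios (plus quadratic
  engineering) and MBC's class count as `2^{M(M−1)}`: beyond M = 3 the
  matrix-based scheme is impractical (4096 classes for M = 4) and the CLI
  refuses it without an explicit override.
* The exact false-positive *percentage* of the Geweke baseline at the cost
  threshold is very sensitive to the (underdetermined) coefficient
  distribution and to N; the package reproduces its qualitative explosion
  relative to the supervised methods rather than any particular printed
  percentage.
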