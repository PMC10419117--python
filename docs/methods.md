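# Methods

## The problem

A two-arm clinical trial collects data and, at the same time, should treat
the patients already enrolled as well as possible. An individualized
treatment rule (ITR) is a map `D(x)` from patient covariates to an arm in
{-1, +1}. This package simulates and evaluates sequential trials in which
the ITR is refit after every patient by outcome-weighted learning (OWL) and
each incoming patient follows the current rule with a controlled
probability, so that the design interpolates between a classical randomized
controlled trial (RCT, maximal exploration) and a greedy contextual bandit
(maximal exploitation).

## Data-generating model

Patients arrive i.i.d. with covariates `X in R^d` drawn from `N(0, Sigma)`
truncated componentwise to `[-1, 1]`. Rewards are

    R | X, A  ~  Normal( m0(X) + T0(X, A),  nu0(X) ),

with main effect `m0`, treatment effect `T0(x, a) = tau(x) * a`
(antisymmetric in the arm by construction), and heteroscedastic variance
`nu0`. The optimal rule is `d*(x) = sign(tau(x))` with `sign(0) = +1`.

Two presets share `d = 10`, unit variances with 0.1 off-diagonal
covariance, `m0(x) = 1 + 2 x1 + x2^2 + 2 x2 x3` and
`nu0(x) = 0.2 x1^2 x3 + 1` (range [0.8, 1.2] on the support):

* `scenario1`: `tau(x) = 0.5 (0.2 - x1 - x2)` (linear contrast);
* `scenario2`: `tau(x) = 0.5 (0.2 - x1^2 - x2)` (quadratic contrast).

Covariates are sampled by rejection of full multivariate-normal draws
against the hypercube. This is exact for the conditional law; the realized
off-diagonal correlations are *attenuated* relative to the nominal 0.1
(about 0.06 empirically) because Sigma is not renormalized after
truncation. The generator does not model covariate shift, non-normal
rewards, or patient selection; what passing tests show is therefore
behavior under an idealized i.i.d. patient stream, not robustness to
real-world enrollment drift.

## The OWL estimator

With records `(X_j, A_j, R_j, pi_j)` (pi the propensity of the realized
arm), the rule `sign(f)` is estimated over linear `f` on a basis expansion
`phi` by minimizing the inverse-propensity-weighted hinge loss

    (1/n) sum_j (R~_j / pi_j) [1 - A_j f(X_j)]_+  +  lambda ||beta||^2,

with an unpenalized intercept. `R~` are rewards residualized against an
ordinary-least-squares fit of `R` on `(1, phi(X))` pooled over arms, a
variance-reduction step that leaves the population minimizer unchanged.
Negative weights are folded in by flipping the reward sign and the arm
label simultaneously, which leaves the objective identical.

Choices that the theory leaves open:

* **Penalty.** `lambda = 1 / n_records` by default, so regularization
  vanishes as data accrue (consistency requires `lambda -> 0`); any fixed
  positive value can be configured.
* **Basis.** Linear terms for `scenario1`; linear plus per-coordinate
  quadratic terms for `scenario2`, matching the form of the respective
  effect contrasts. The intercept is never penalized.
* **Solver.** The weighted hinge + ridge problem is solved in the dual by a
  dedicated SMO routine (`_solver.py`) with second-order working-set
  selection, an exact unpenalized intercept, and warm starts from the
  previous refit's dual vector. On random instances its objective agrees
  with libsvm's SMO and with a generic SLSQP solve of the slack formulation
  to ~1e-7.
* **In-loop tolerance.** Sequential refits stop at a maximal-violating-pair
  gap of 0.02 on the scaled dual (`TrialConfig.refit_tol`); the final
  deliverable rule is always refit at the tight `OWLConfig.tol` (1e-6
  default). Measured against exactly solved refit sequences this changes
  about 0.5% of intermediate decisions and the coefficient direction by
  cosine < 1e-4, far below replicate noise in any reported metric.

## Exploration policies

Positivity is enforced by the truncation schedule
`eps_i = eps0 * i^{-(1-theta)/4}`, `eps0 in (0, 0.5]`, `theta in (0, 1]`,
indexed by the main-trial order i (pilot patients are fair-coin randomized
with propensity 0.5 and no schedule). Every stochastic policy keeps the
follow probability `p_i` inside `[eps_i, 1 - eps_i]`, which the engine
asserts at every step.

* **Epsilon-greedy (`srat_e`).** `p_i = 1 - eps_i`, the
  exploitation-maximal choice inside the band. The band only constrains
  `p_i`; pinning it at the ceiling is what makes `eps0 = 0.5, theta = 1`
  reduce exactly to an RCT (`p_i = 0.5`), so that choice is forced by the
  RCT special case.
* **Boltzmann (`srat_b`).** Per-arm ridge regressions with identity prior
  (`W_a = I + Phi' Phi`, `Y_a = Phi' R`, `beta_a = W_a^{-1} Y_a`; only the
  realized arm's state is updated each step) give an upper confidence
  bound `U_a = phi' beta_a + alpha (phi' W_a^{-1} phi)^{1/2}` with constant
  width `alpha = 0.2`. The benefit is `B = U_d - U_{-d}` for the OWL rule's
  arm d. When `B >= 0` (the two models agree) `p_i = 1 - eps_i`; otherwise
  `p_i = max(eps_i, logit^{-1}(B / gamma_i))` with temperature
  `gamma_i = 0.999^i` (slow decay so the soft assignment does not collapse
  early). The ridge basis is the same expansion OWL uses, with an explicit
  intercept column; `beta_a` is recomputed by a fresh linear solve after
  each update (p <= 21, so caching buys nothing).
* **LinUCB (`linucb`).** The two-arm disjoint-model variant: the arm with
  the larger UCB, deterministically; the eps, gamma -> 0 limit of the
  Boltzmann map. Because its propensities are degenerate (recorded as 1),
  its records can never enter an IPW-weighted OWL objective; LinUCB runs
  use the ridge model end to end and their rule checkpoints are the
  ridge-mean rules `sign(phi . (beta_+ - beta_-))`.
* **`rct`.** The `eps0 = 0.5, theta = 1` epsilon-greedy special case.

Ties (`sign(0)`, equal UCBs) resolve to +1 everywhere: the boundary has
probability zero under the continuous covariate law, but determinism
requires a convention.

## Trial engine

Pilot: n0 patients (default 30, about the smallest count that supports the
21-column scenario-2 design), arms i.i.d. fair-coin (no forced balance),
propensity 0.5. Main loop for i = 1..n: draw `X_i`; evaluate the rule in
force `d = sign(f_{i-1}(X_i))`; get `p_i` from the policy; draw the follow
indicator `I_i` (+1 with probability `p_i`); assign `A_i = I_i d`; record
the realized-arm propensity (`p_i` if followed, else `1 - p_i`); observe
the reward; refit. The bookkeeping identity `A_i I_i = f_{i-1}`-decision is
asserted in tests. Refit cadence is configurable (`refit_interval`, default
every patient; `None` disables refits entirely, which is only appropriate
when the assignment law does not depend on the rule, as in the RCT
configuration).

### Replay of logged randomized data

For a logged table (columns `X1..Xd, A, R, propensity`) whose arms were
randomized independently of covariates, the engine replays the adaptive
design: the first n0 kept records come from uniform suggestions; afterwards
each candidate receives the suggestion `I_i * d(x)` and is kept only when
the logged arm matches (expected keep rate 0.5 under fair-coin logging).
The kept record's propensity is the suggestion probability of the realized
arm — the probability the replay mechanism actually used — and that is what
enters subsequent refits; the alternative of keeping the logging propensity
(0.5) is available by editing the kept table before refitting, but is not
the realized mechanism. A K-fold wrapper (`kfold_replay_value`, default 5
folds) replays on K-1 folds and scores the final rule on the held-out fold
with the self-normalized IPW estimator.

## Evaluation

`V(f)` is estimated on a Monte-Carlo covariate sample (default 100,000,
configurable down for speed) by averaging the *conditional-mean* reward
`Q0(X, sign f(X))` — the same expectation as averaging noisy rewards with
strictly smaller variance; the noisy variant is available behind
`noise_free=False`. One shared sample per replicate is reused across all
checkpoints and policies, so comparisons are paired: `V(f*) - V(f*)` is
exactly 0 and orderings are not blurred by independent sampling noise.
`V(f*)` is always computed on the same paired sample, never treated as a
known constant.

* test regret: `V(f*) - V(f_n)`;
* training regret: `(1/n) sum_i [V(f_{i-1}) - R_i]`, using the per-step
  checkpoints (with coarser refit cadence the most recent checkpoint is
  used, a documented bias);
* false decision ratio: disagreement with `d*` (on the realized training
  assignments, or the final rule over the test sample);
* weighted tradeoff: `lam * test + (1 - lam) * train`, `lam in [0, 1]`;
* rate arithmetic: test regret decays as `n^{-theta/2}` up to log factors,
  training regret as `n^{-(1-theta')/4}`; the rates match at
  `theta = 1/3` with common exponent 1/6.

## Sweeps and the sample-size search

`run_sweep` crosses policy, eps0, theta and n grids with per-replicate
seeds derived from `(base_seed, cell, replicate)`; results are a pure
function of the specification, and aggregation (mean and standard error
over replicates) is order-independent. `sample_size_search` scans an
aggregated table for the smallest n at which some theta meets both
correct-decision requirements simultaneously, reporting the largest
qualifying theta at that n (larger theta yields the better final rule);
raising either requirement can only increase the returned n.

## Problem sizes used by the shipped checks

The package's own test suite runs the simulation-backed checks at reduced
scale, chosen as the smallest configurations at which the qualitative
effects are resolved against replicate noise: tradeoff monotonicity at
n = 200 with 40 replicates per theta; the theta-endpoint deltas at n = 800
with 40 replicates; the policy ordering at n = 400 with 32 replicates;
value estimation on 4,000-point paired test samples. Companion cells share
per-replicate seed keys (common random numbers), so ordering checks compare
paired replicates. The acceptance script reports the pure-randomization
training accuracy at the full n = 800 with 100 replicates. Full-replication
(1,000-iteration, 100,000-point evaluation) runs reproduce the same
quantities by raising `n_reps` and `mc_size` in `SweepSpec`.

## Known limitations

* Linear decision rules only (no RKHS kernels), two arms, single stage; no
  early stopping or interim inference.
* Linear-kernel OWL in these scenarios reaches ~93% agreement with the
  optimal rule at n = 2000 under pure randomization and ~97.5% at
  n = 20000; convergence is real but slow, so small-n rules are noticeably
  noisy.
* The replay construction assumes the logged arms are independent of
  covariates; with confounded logs the keep mechanism would bias the
  stream.
* LinUCB's training regret can be negative: its realized rewards are
  compared against the value of its concurrent ridge rule, and a greedy
  assignment can outperform that rule's population value.
* With the intercept column in the ridge basis the linear ridge model is
  well specified in `scenario1`, so LinUCB's rule is strong there and its
  training regret is statistically indistinguishable from (at moderate n,
  slightly above) the Boltzmann policy's, which profits from following the
  ridge-preferred arm exactly where the two models disagree.
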