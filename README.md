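# srat — sequentially rule-adaptive trials

`srat` simulates two-arm adaptive clinical trials that learn an
individualized treatment rule (ITR) *while the trial runs*. After a small
purely randomized pilot, the rule `D(x) = sign(f(x))` is refit by
outcome-weighted learning (OWL) after every patient, and each incoming
patient follows the current rule with a controlled probability, so the
design spans the whole range between a classical randomized controlled
trial (maximal exploration, best final rule) and a greedy contextual
bandit (maximal in-trial benefit). The package is aimed at biostatisticians
studying adaptive designs: it ships the synthetic scenarios, the
exploration policies, the regret/value evaluation suite, a replay
construction for logged randomized data, and a sweep/sample-size toolkit.

## The method

OWL turns reward maximization into weighted classification. Given records
`(X_j, A_j, R_j, pi_j)` with propensities `pi_j`, the decision function
solves

    f_i = argmin_f (1/(n0+i)) sum_j (R~_j / pi_j) [1 - A_j f(X_j)]_+ + lambda ||beta||^2

over linear `f` on a basis expansion, where `R~` are rewards residualized
against a pooled least-squares main-effect fit and negative weights are
handled by flipping reward and arm together. Patient i follows the current
rule (`A_i = I_i D_{i-1}(X_i)`, `I_i = +1` with probability `p_i`) under
one of four policies:

* `srat_e` — epsilon-greedy: `p_i = 1 - eps_i` with
  `eps_i = eps0 * i^{-(1-theta)/4}`;
* `srat_b` — Boltzmann: an inverse-logit of the UCB-based benefit from
  per-arm ridge models, truncated to `[eps_i, 1 - eps_i]`;
* `linucb` — deterministic two-arm LinUCB (the eps, gamma -> 0 limit);
* `rct` — pure randomization (`eps0 = 0.5, theta = 1`).

Performance is measured by the training regret
`(1/n) sum_i [V(f_{i-1}) - R_i]` (what enrolled patients lost) and the test
regret `V(f*) - V(f_n)` (what the final rule loses on the population);
their decay exponents `theta/2` and `(1-theta')/4` balance at
`theta = 1/3`. See `docs/methods.md` for the full model and the numerical
choices.

## Worked example

```python
import numpy as np
from srat import (TrialConfig, run_trial, evaluate_trial, scenario,
                  sample_covariates)

cfg = TrialConfig(scenario="scenario1", policy="srat_e",
                  policy_params={"eps0": 0.1, "theta": 0.5},
                  n0=30, n=400, seed=7)
result = run_trial(cfg)

spec = scenario("scenario1")
X_test = sample_covariates(20_000, spec, np.random.default_rng(8))
for k, v in evaluate_trial(result, spec, X_test).items():
    print(f"{k:>14s}  {v: .4f}")
```

prints

```
  train_regret   0.0061
   test_regret   0.0429
     train_fdr   0.3050
      test_fdr   0.1615
 train_correct   0.6950
  test_correct   0.8385
   mean_reward   1.4790
```

Reading: over the 400 main-trial patients the realized rewards trailed the
concurrent rule's population value by only 0.006 reward units on average
(the policy is fairly greedy: 69.5% of in-trial assignments matched the
optimal rule, against 50% for an RCT), while the final learned rule gives
up 0.043 reward units per patient relative to the optimal rule and decides
83.9% of a fresh 20,000-patient population correctly. The same interface
drives the other policies, scenario 2 (quadratic basis), replicate sweeps
(`srat.run_sweep`), the sample-size search (`srat.sample_size_search`) and
the logged-data replay (`srat.replay_trial`, `srat.kfold_replay_value`).
A `srat` console script exposes `simulate`, `run`, `sweep`, `sample-size`,
`replay` and `rates` subcommands over the same functions.

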