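# obdesign

Utility-based Bayesian dose optimization for seamless phase I/II oncology
trials, with estimand-aware handling of intercurrent events.

## The problem

Classical phase I designs chase the maximum tolerated dose (MTD), assuming
efficacy rises monotonically with toxicity. For targeted therapies, antibody
drug conjugates and immunotherapies that assumption often fails: activity
plateaus while toxicity stays benign, and the right target is instead the
**optimal biological dose (OBD)** — the dose with the best risk–benefit
trade-off. `obdesign` is for trial statisticians designing and analyzing
such dose-optimization trials: it provides the Bayesian outcome model, the
utility-based selection rules, a simulator for operating characteristics,
and — its distinctive piece — an **estimand layer** that makes explicit how
intercurrent events (ICEs: deaths, toxicity discontinuations, subsequent
anticancer therapy, surgery, antidrug antibodies, dose switching, ...) are
absorbed into the analysis before any posterior is computed.

## The model

Each patient yields binary efficacy Ye and toxicity Yt, combined into K = 4
categories: Y=1 ↔ (0,1), Y=2 ↔ (0,0), Y=3 ↔ (1,1), Y=4 ↔ (1,0). Per dose j,

    Y | d=j ~ Multinomial(π_j1, …, π_jK),   π_j ~ Dirichlet(a_1, …, a_K),

with the vague prior a_k = 1/K (prior sample size 1). The posterior is
conjugate: Dirichlet(a_1 + n_j1, …, a_K + n_jK). Dose desirability is the
mean utility

    U_j = Σ_k ψ_k π_jk,

with elicited scores ψ (default (0, 10, 60, 100)); the marginal trade-off
U_j^M = π_e,j − w·π_t,j is an exact special case via an affine embedding.
A dose is inadmissible if Pr(π_t,j > φ_t | D) > δ_t (toxic) or
Pr(π_e,j < φ_e | D) > δ_e (futile); both marginals are exact Beta laws by
Dirichlet aggregation. The MTD is the dose whose isotonically estimated
toxicity probability is closest to φ_t, and

    OBD = argmax_{j ∈ A} U_j,   subject to j ≤ MTD.

Before any of this, each patient trajectory is reduced to one (Ye, Yt)
contribution under a configured per-ICE strategy — treatment policy,
composite, hypothetical, while-on-treatment, or principal stratum — with a
precedence order deciding which of several events is decisive. The same
data under different strategy maps are different estimands, and the package
computes them side by side.

## Worked example

Six patients at one dose — counts (2, 1, 0, 3) over the four categories:

```python
import obdesign as od

prior = od.make_prior(4, "vague")
post = od.update_posterior(prior, od.OutcomeCounts(1, [2, 1, 0, 3]))
tox = od.marginal(post, "toxicity")
u = od.posterior_expected_utility(od.UtilitySpec(od.DEFAULT_SCORES), post)
print(post.concentrations)            # [2.25 1.25 0.25 3.25]
print(tox.alpha, tox.beta, tox.mean)  # 2.5 4.5 0.357...
print(u.value)                        # 50.357...
print(od.prob_exceeds(tox, 0.35))     # 0.485...
```

The posterior toxicity marginal is Beta(2.5, 4.5) (mean 0.357), the
posterior expected utility is 50.357 on the 0–100 elicitation scale, and
the probability that the true toxicity rate exceeds the 0.35 limit is
0.485 — below the δ_t = 0.95 cutoff, so the dose stays admissible.

The `examples/` directory holds one short script per capability:
posterior utilities (`01`), estimand comparison on a fixed dataset (`02`),
operating characteristics of a 27-patient utility-guided trial (`03`), and
tipping-point sensitivity analysis (`04`). A complete protocol document,
including the simulation scenario, is in `examples/case_study.yaml`; the
`obdesign` command line runs it:

```
obdesign boundaries --phi 0.30
obdesign simulate-oc --config examples/case_study.yaml --seed 1 --out out/
```

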