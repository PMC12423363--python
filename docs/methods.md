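# Methods

## Outcome model

Per dose j, the four efficacy×toxicity categories follow a multinomial law
with probability vector π_j carrying a Dirichlet prior. Everything
downstream is conjugate and closed-form: no MCMC anywhere. Two priors are
built in. The *vague* prior sets a_k = 1/K so the prior carries the weight
of a single patient; it is the default for design operation. The *Haldane*
prior (all a_k = 0) exists for prior-sensitivity analysis; it is implemented
as the exact limit, and any posterior evaluation touching a category with
zero concentration and zero count raises instead of silently adding an
epsilon — hidden regularization would defeat the point of a sensitivity
prior.

Marginal toxicity and efficacy probabilities are exact Beta laws obtained by
summing Dirichlet components over the flag partition (aggregation property),
so admissibility tail probabilities are regularized incomplete beta
functions, not approximations.

The (Ye,Yt) ↔ category bijection is fixed for K = 4. Larger outcome spaces
are supported but the caller must supply the category→flags map, since no
canonical coding exists beyond the binary×binary case.

### Utility scores

Default ψ = (0, 10, 60, 100): the toxic non-responder scores 0 (least
desirable), the clean responder 100 (most desirable), and a responder with
toxicity (60) is preferred to a non-responder without (10) — appropriate
where toxicity is manageable and response drives survival. The literature
this convention comes from is internally inconsistent on the labeling (one
passage attaches the maximum score to ψ1); we follow the guideline ordering
ψ1 ≤ … ≤ ψ4 throughout and treat the other passage as a typographical slip.
Scores are always reported on the elicitation scale, never rescaled.

The marginal trade-off π_e − w·π_t embeds exactly as ψ(e,t) = lo +
(hi−lo)(e − w·t), making the mean utility an affine, order-preserving
transform of the marginal utility (slope hi−lo > 0); rankings therefore
agree identically. For w > 1 the embedded (1,1) score falls below the (0,0)
score — clinically unusual, so the score set is flagged `relaxed` and a
warning issued rather than an error.

## Selection rules

- **Admissibility**: toxic if Pr(π_t > φ_t | D) > δ_t, futile if
  Pr(π_e < φ_e | D) > δ_e; both checks always run and both reasons are
  recorded. Screening applies from the first cohort: under the vague prior
  a data-free dose has diffuse Beta(0.5, 0.5) marginals whose tails cannot
  cross a 0.95 cutoff, so untried doses are never excluded prematurely.
- **MTD**: weighted isotonic (nondecreasing) regression of the posterior
  toxicity means, weighted by posterior pseudo-counts (Beta α+β per dose) —
  the Bayesian summary being isotonized — with sample-size weights available
  by argument. The MTD is the dose whose fitted value is closest to φ_t;
  all argmax/argmin ties in the package break toward the lower dose index
  (conservative dosing).
- **OBD**: utility argmax over admissible doses at or below the MTD; an
  empty feasible set returns none (trial terminated without an OBD).
- **BOIN boundaries**: the optimal-interval closed form with default
  interval bounds φ1 = 0.6φ, φ2 = 1.4φ; at φ = 0.30 this yields
  λ_e = 0.2364…, λ_d = 0.3586…, i.e. the familiar 0.236/0.359 protocol
  thresholds at 3 decimals. Comparison conventions: escalate when the
  observed rate ≤ λ_e, de-escalate when ≥ λ_d.
- **Assignment**: deterministic max-utility (default), adaptive
  randomization with ω_j ∝ U_j over the admissible set, or equal
  randomization. Adaptive weights require nonnegative utilities; scales
  admitting negatives are shifted by the scale minimum, logged explicitly.
  By linearity of the utility in π, the plug-in posterior-mean utility and
  the exact posterior expected utility coincide, so there is no ambiguity
  about which functional drives randomization weights.

## Estimand layer

A trajectory is a time-sorted list of (efficacy, toxicity) assessments plus
intercurrent events. Reduction to one (Ye, Yt) pair:

1. An event at or before the first efficacy-positive assessment is
   *decisive-eligible*; an event after a recorded response is not an ICE at
   all (the endpoint was already achieved) and is skipped.
2. Eligible events are ordered by the configured precedence (ties by event
   time), and the first one's strategy handles the record. The default
   precedence orders by clinical severity/terminality (death first,
   nonadherence last) and is fully configurable — only the precedence, never
   the raw event-list order, affects the result.
3. Strategies: *treatment policy* takes the best response over all
   assessments; *composite* sets Ye = 0 and forces Yt = 1 only for event
   types in `composite_toxicity_types` (default: death, toxicity
   discontinuation — other composite events keep observed toxicity);
   *while-on-treatment* uses assessments up to and including the event time;
   *hypothetical* substitutes the counterfactual outcome and errors on real
   data without one (no imputation model is smuggled in); *principal
   stratum* excludes patients in the would-experience stratum and errors
   when the stratum is unknown — oracle strata exist only in simulation, and
   identifying them from baseline covariates on real data is out of scope.

"Best response" means any efficacy-positive assessment sets Ye = 1 (the
responder definition used for objective-response endpoints). Dose switching
under treatment policy attributes the patient to the initially assigned
dose (intention-to-treat reading).

The tipping-point analysis flips the s most favorable *pending* (unresolved
final outcome) contributions to the least favorable category, s = 0..max,
recomputing utilities and the OBD each time; the smallest OBD-changing s is
reported, with ties among equally favorable records broken by patient id
for determinism.

## Simulator

The generator emulates the data-generating structure the analysis assumes:
a per-dose four-category multinomial truth with ICEs superimposed. Per
patient: the factual category is drawn once and doubles as the
counterfactual (ICEs affect the *observability* of assessments, not the
latent outcome); each ICE type occurs independently with its per-dose
probability, its Bernoulli draw recorded as the latent stratum; event times
are exponential truncated to the assessment window (default mean: half the
window) — the literature specifies only binary occurrence, so any timing
law is a modeling choice, and the truncated exponential front-loads events
realistically. Assessments sit at the response time (uniform over the
56-day window), the toxicity time (uniform over the 28-day DLT window) and
the window end, with cumulative flags; nothing is observed after death, and
assessments after any other ICE survive with probability `followup_prob`
(default 0.5). The 28-day DLT window is carried as protocol metadata; the
binary-outcome engine does not model within-window timing beyond event
ordering.

What the generator does **not** emulate: late-onset/delayed outcomes and
time-to-event likelihoods, graded (non-binary) toxicity, correlated ICEs,
PK/exposure, and real accrual patterns. Passing tests therefore demonstrate
internal consistency of the design machinery under its own assumptions, not
performance on trajectories violating them.

Trial conduct: optional accelerated titration (single-patient cohorts until
the first observed toxicity or a trigger dose level, default 5), then
cohorts of `cohort_size`. Each cohort is resolved through the estimand
layer, posteriors refreshed, and the next dose chosen by the assignment
policy among admissible doses below the per-dose cap, with a safety
constraint: untried doses open one level at a time (an unconstrained
max-utility rule could leap to an untried high dose). The per-dose cap
(default 12) removes a dose from assignability without ending the trial.
Stopping: the sample-size cap, an empty admissible set (early termination),
or no assignable dose. Toxicity-only mode replaces utility assignment with
BOIN interval moves of one level.

All randomness flows from numpy `SeedSequence`s; operating characteristics
spawn one child stream per replicate, so results are bit-reproducible given
(seed, config) and independent of replicate count ordering.

## Problem sizes and numerics

The shipped test suite uses 10^5-draw Kolmogorov–Smirnov checks for the
Beta marginals, 10^6-draw Monte-Carlo oracles for posterior utilities and
tails, 500 paired replicates for the composite-vs-treatment-policy
dominance property, and 200 replicates of 300-patient trials for OBD
recovery — sizes at which the sampling noise is far below the assertion
margins. Probability vectors are validated to 1e-6; utility/argmax ties use
a 1e-12 absolute tolerance; all floats are 64-bit.

## Known limitations

- Hypothetical and principal-stratum estimands work only where
  counterfactuals/strata exist (simulation); real-data use raises.
- The composite ≤ treatment-policy utility dominance holds pointwise by
  construction of the default scores; exotic score vectors violating the
  monotonicity invariants are rejected at `UtilitySpec` construction.
- "Maximum of 12 patients per cohort" in the motivating protocol is read as
  a per-dose cap (the usual convention); the wording is ambiguous and the
  cap is configurable.
- No dose extrapolation beyond the studied grid, no intrapatient
  escalation, no PK integration.
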