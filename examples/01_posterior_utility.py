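"""Posterior dose desirability from observed outcome counts.

Six patients at one dose: two toxic non-responders, one with neither
outcome, three responders without toxicity.  The vague 1/K prior plus these
counts give the Dirichlet posterior, its Beta toxicity/efficacy marginals,
and the posterior expected utility under the elicited scores (0, 10, 60, 100).
"""

import obdesign as od

prior = od.make_prior(4, "vague")
counts = od.OutcomeCounts(dose_index=1, counts=[2, 1, 0, 3])
post = od.update_posterior(prior, counts)

tox = od.marginal(post, "toxicity")
eff = od.marginal(post, "efficacy")
spec = od.UtilitySpec(od.DEFAULT_SCORES)
u = od.posterior_expected_utility(spec, post)

print(f"posterior concentrations: {post.concentrations}")
print(f"toxicity marginal:  Beta({tox.alpha}, {tox.beta})  mean {tox.mean:.3f}")
print(f"efficacy marginal:  Beta({eff.alpha}, {eff.beta})  mean {eff.mean:.3f}")
print(f"posterior expected utility: {u.value:.3f}")
print(f"Pr(toxicity rate > 0.35): {od.prob_exceeds(tox, 0.35):.3f}")
# The utility (~50 of 100) says this dose trades its 36% posterior toxicity
# rate against a 50% response rate; the toxicity tail probability feeds the
# admissibility screen.
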