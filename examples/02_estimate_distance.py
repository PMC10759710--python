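"""Recovering a known scaled distance with the three estimators.

Simulates one mtDNA-scale dataset (15,629 transversion-free sites, Gamma
site rates) at a true distance of 5% of the total phylogeny edge length,
then runs the joint MLE (Method 1), the conditional estimator (Method 2)
and the Gamma-prior MAP (Method 3), with the Cramer-Rao bound for scale.
"""

import numpy as np

from parityclock import GammaRates, crb_p, fit_nb_prior, sample_rates, simulate_counts
from parityclock.estimators import estimate

P_TRUE = 0.05
N_SITES = 15629

lam = sample_rates(GammaRates(), N_SITES, seed=42)
problem = simulate_counts(lam, P_TRUE, seed=43)
print(f"simulated {N_SITES} sites at true p = {P_TRUE} "
      f"({problem.parity.mean():.3f} of sites mismatch)\n")

for method, label in (("mle", "Method 1 (joint MLE)"),
                      ("conditional", "Method 2 (conditional)"),
                      ("gamma_map", "Method 3 (Gamma MAP)")):
    est = estimate(problem, method=method)
    print(f"{label:28s} p_hat = {est.p_hat:.5f}  ({100 * est.p_hat:.2f}% of tree length)")

prior = fit_nb_prior(problem.counts)
print(f"\nNB-fitted rate prior: alpha = {prior.alpha:.3f}, beta = {prior.beta:.3f} "
      f"(prior mean {prior.mean:.2f} transitions/site/tree)")
sd = np.sqrt(crb_p(np.maximum(lam, 1e-12), P_TRUE))
print(f"Cramer-Rao bound: sd(p_hat) >= {sd:.5f} for unbiased estimators")
print("All three estimates land within a few CRB standard deviations of 0.05;")
print("Method 1 sits slightly high (its many nuisance rates bias it upward).")
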