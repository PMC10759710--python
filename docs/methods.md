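# Methods

## Model and assumptions

`parityclock` estimates the scaled distance *p* between two aligned
sequences, measured as a fraction of the total edge length of a large
reference phylogeny of one of the species. The model rests on five
assumptions:

1. **Molecular clock** — transitions accumulate at a constant rate over
   time and across lineages.
2. **Poisson counts** — the number of transitions at site *i* over a
   branch of length *t* is Poisson(λ_i·t), with a site-specific rate λ_i
   (memoryless accumulation).
3. **Transitions only** — sites carrying transversions (anywhere in the
   phylogeny, or between the target pair) are removed rather than
   modelled; transversions are rare enough in mtDNA that masking costs
   ~6% of sites.
4. **Site independence** — counts at different sites are independent.
5. **Complete phylogeny** — the reference tree annotates every
   substitution along its branches, so the per-site transition totals X_i
   are observed without error and are Poisson(λ_i) after normalising the
   tree to total length 1.

The pair comparison only reveals the *parity* Z_i of the latent count
Y_i ~ Poisson(λ_i·p): distinct same-class bases mean an odd number of
transitions. Parity of a Poisson(Λ) variable is Bernoulli((1−e^(−2Λ))/2),
which yields the joint likelihood used throughout. The observable per
site saturates as λ_i·p grows (a coin flip carries no signal), which is
why information about large *p* decays exponentially — quantified exactly
by the Fisher information block formulas in `fisher.py`.

## Estimators and numerical choices

**Method 1 (joint MLE).** For each candidate *p* on a log grid
(default [1e-4, 1], 200 points — observed hominin/chimp distances span
~0.008–0.12, comfortably interior), each site's rate is profiled out by
solving x = λ + 2pλ/((−1)^z e^{2λp} + 1). The solver is a vectorised
bisection with analytically guaranteed brackets ([x/(1+2p), x] for even
parity, (x, x+1] for odd), run simultaneously for all grid points and all
*unique* (x, z) pairs (counts are small integers, so a 15,629-site
problem collapses to ~10² unique pairs). A bounded scalar refinement
between the best grid point's neighbours polishes p̂. At an interior
optimum the solution satisfies Σλ̂ = ΣX and a vanishing score in *p*;
both residuals are returned as diagnostics. The estimator carries the
classic incidental-parameter handicap: one nuisance rate per observation.
Measured on 300 mtDNA-scale replicates its relative bias is ≈ +0.5% of p
at p = 0.01 but ≈ +5% at p = 0.05 and ≈ +10% at p = 0.1 — visible in the
benchmark and consistent with its behaviour on real chimpanzee-distance
data, where it reads ~14% above the other methods.

**Method 2 (conditional).** Estimating λ_i from X_i alone and treating
the pair's transitions as a binomial sub-sample (Y_i|X_i ~ Bin(X_i, p))
gives Z_i|X_i ~ Bernoulli((1−(1−2p)^{X_i})/2) with no dependence on λ.
The score is aggregated over sites (a Poisson approximation to the sum of
independent Bernoullis — Le Cam's theorem — which also removes any need
to special-case X_i = 0, Z_i = 1 sites) and solved by bisection on
[0, ½ − 1e-9] with tolerance 1e-12; the left side Σ(1−2p)^{X_i} is
non-increasing in *p*, asserted at run time. The thinning construction is
only a probability model for p < ½, so parity fractions too high for it
clamp to the boundary with `boundary_hit` set and a warning — never
silently.

**Method 3 (Gamma MAP).** With λ_i ~ Γ(α, β) (rate convention) and a
flat prior on p ≥ 0, the rates integrate out in closed form:
l(p) = Σ log(1 + (−1)^{Z_i}(1 + 2p/(β+1))^{−(X_i+α)}). Differentiating
shows stationary points satisfy Σ (X_i+α)/((−1)^{Z_i}(1+2p/(β+1))^{X_i+α}+1) = 0;
because that score is singular at p = 0 for odd-parity sites, the
implementation maximises the objective (log-grid on [1e-8, 20] plus
bounded refinement) and reports the score residual post hoc (≲1e-6 at
interior optima). The cap p_max = 20 is far beyond any distance of
interest (chimpanzee ≈ 0.11). Hyperparameters come from intercept-only
Negative-Binomial maximum likelihood on the counts (statsmodels NB-2 with
BFGS and method-of-moments starts): the Gamma-Poisson mixture makes the
counts exactly NB with E X = α/β and Var X = α/β + α/β². Underdispersed
count vectors (variance ≤ mean) lie outside the NB family; the fit then
falls back to a near-Poisson prior with β clamped at 10⁶, preserving the
mean, and warns.

**Numerical conventions.** All exponential differences use
expm1/log1p-style evaluation; exponents are clamped at 700 before
exponentiation; impossible configurations (λ_i = 0 with X_i > 0, or odd
parity at λ_i·p = 0) yield −∞ log-likelihood. p = 0 is an admissible
estimate (it is the exact optimum whenever no site mismatches); the
additive constant −Σ log X_i! − n log 2 is dropped from all likelihoods.

## Fisher information and the CRB

The information matrix is diagonal in the rates with a single coupling
column to *p*; the Schur complement gives the closed-form bound
CRB(p) = [4 Σ λ_i²/(e^{4λ_i p} − 1 + 4p²λ_i)]^{−1}, verified in the tests
against a Monte-Carlo negative expected Hessian (10⁶ draws, central
differences with steps 0.02 in λ and 0.002 in *p* — the smaller *p* step
keeps O(h²) truncation below the Monte-Carlo noise) and against dense
matrix inversion for n ≤ 50. The bound applies to unbiased estimators;
benchmark MSEs of Methods 2–3 track it closely while Method 1 departs
from it as *p* grows.

## What the synthetic data emulates

**Rate distributions.** The default Gamma(shape 0.23, rate 0.164) —
mean ≈ 1.40 transitions per site per tree length, strongly heavy-tailed —
reproduces the site-rate profile fitted to human-mtDNA phylogeny counts.
The two-point alternative (0.1 with probability 0.11, 11.87 otherwise)
implements its published parameterisation verbatim; note those published
values do not actually match the Gamma's mean of 1.4 (the probabilities
would need swapping), a documented discrepancy we preserve rather than
repair.

**Raw tier.** X and the latent Y are drawn directly as Poissons — the
model holds exactly, so this tier measures pure estimator error. It is
the setting of the benchmark and recovery studies.

**Sequence tier.** Each site evolves on {A, C, G, T} under a site-scaled
K2P or TN93 chain, simulated by uniformisation (a Poisson number of
virtual events per site at the maximal exit rate, then vectorised jump
rounds; for K2P the thinning is exact, making per-site transition counts
exactly Poisson). Defaults: transition rate 1 (so a site's scale factor
is its expected transitions per tree length), per-target transversion
rate 1/(2·20). The ti/tv rate ratio of 20 was chosen because, over one
tree length with Gamma scales, it yields ≈ 5.9% transversion-carrying
sites — matching the 940/16,569 observed in the human mtDNA tree. The
exact published K2P/TN93 parameter extraction lives in an unavailable
supplement, so these defaults are declared here and overridable in
`SubstitutionModelSpec`. This tier feeds the robustness checks: the
estimators see only the masked sequence pair, so hidden multiple hits
and residual transversion effects are part of the test. A phylogeny
summary is generated by running the same chain over one full tree
length; treating the tree's total edge length as a single lineage gives
the correct marginal per-site count distribution, which is all the
estimators consume (no tree topology is simulated — the methods never
look at one).

**What passing does not show.** The generator draws rates i.i.d. across
sites and evolves a single lineage; real mtDNA has rate autocorrelation
along the molecule, selection, sequencing error, and a reference
phylogeny that is itself reconstructed. Tests passing here validate the
estimators under their stated model plus K2P/TN93 misspecification, not
those additional real-data effects.

**Rate floors.** When rates are read off an observed count table, the
~2/3 of sites with zero counts would get rate 0; `fit_epsilon_ks` picks
their floor ε by minimising the two-sample Kolmogorov–Smirnov statistic
between simulated and observed count distributions over a log grid
(default 50 points in [1e-3, 1]), with one shared seed across candidates
so the sweep is paired and deterministic.

## Pipeline conventions

Coordinates are 1-based inclusive (rCRS convention), stated in the count
table header. Sequences must arrive pre-aligned to the phylogeny's
coordinate system; alignment is out of scope. Ambiguity codes beyond
A/C/G/T, gaps and N are all treated as unusable and masked —
conservative under the masking scheme. Bootstrap SDs resample sites with
replacement, jointly for X and Z, B = 100 by default. TMRCAs from many
modern-sequence comparisons are combined by uniform (unweighted)
averaging; for panels of diverse origins this approximates the proximity
weighted alternative well, and weighting is deliberately out of scope.
Calibration uses μ = 1.57×10⁻⁸ substitutions/site/year and 1.4
substitutions per site over the phylogeny (total tree length
1.4/μ ≈ 89.2 Myr); both are overridable per run.

## Benchmark and test scale

Replicated studies default to desk scale: 500 replicates per distance in
the benchmark (the full 10,000-replicate setting sits behind a flag), 50
replicates for recovery means, 100 for the K2P robustness t-test, 200
for the acceptance script's RMSE table. Squared-error comparisons use
one-sided paired Wilcoxon signed-rank tests, Bonferroni-corrected over
all ordered method pairs at each distance.

Two findings from these studies are worth stating plainly. First, the
joint MLE's incidental-parameter bias means its mean estimate sits many
standard errors above the truth for p ≥ 0.05 at mtDNA scale; it is kept
because it is the natural frequentist baseline, with its bias documented
rather than patched. Second, under rates drawn from exactly the Gamma
family that Method 3 assumes, Method 3's squared error is marginally
*smaller* than Method 2's (fractions of a percent, but consistently so
in paired comparisons); Method 2's advantages are its speed, its freedom
from distributional assumptions, and equal robustness under the
sequence-level simulations.

## Known limitations

* Transversions are masked, not modelled; taxa with high transversion
  loads would lose many sites.
* The reference phylogeny's counts are taken as exact; annotation errors
  propagate directly into the rate estimates.
* Introgression is outside the model: distances for introgressed
  lineages date the mtDNA coalescence, not the population split.
* Confidence intervals are bootstrap-only; no profile-likelihood or
  posterior intervals are provided.
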