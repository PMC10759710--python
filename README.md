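# parityclock

**Dating the common ancestor of two sequences from the parity of Poisson
transition counts, using site rates learned from a large phylogeny.**

## The problem

Estimating the time to the most recent common ancestor (TMRCA) of two
lineages — say, a modern human and a Neanderthal mtDNA genome — usually
means reconstructing a phylogeny containing both sequences and dating its
nodes. `parityclock` takes a different route: it assumes a large, detailed
reference phylogeny already exists for *one* of the species (for human
mtDNA, a Phylotree-style tree annotating every substitution on every
branch) and uses only two per-site summaries:

* **X_i** — the number of transitions (A↔G, C↔T) observed at site *i*
  across the entire reference phylogeny, modelled as Poisson(λ_i) with
  tree edges normalised to total length 1;
* **Z_i** — whether the two target sequences differ at site *i*. Under a
  transitions-only model this is the *parity* of the latent transition
  count Y_i ~ Poisson(λ_i · p), where *p* is the scaled distance between
  the sequences (fraction of total phylogeny edge length).

The parity of a Poisson(Λ) variable is Bernoulli((1 − e^(−2Λ))/2), so the
joint log-likelihood of (p, λ⃗) given (X⃗, Z⃗) is

```
l(p, λ) = Σ_i [ −λ_i + X_i log λ_i + log(1 + (−1)^{Z_i} e^{−2 λ_i p}) ] + const.
```

Sites where a transversion occurred (in the phylogeny or between the
pair) violate the transitions-only model and are masked out; for human
mtDNA that leaves 15,629 of 16,569 sites.

## Estimators

* **Method 1 — joint MLE** (`fit_mle`): grid sweep over *p*, profiling
  each λ_i out by solving its stationarity equation numerically, plus a
  local refinement pass. Statistically handicapped by the 15,629 nuisance
  rates (its upward bias grows with *p*).
* **Method 2 — conditional** (`fit_conditional`): treats the pair's
  transitions as a binomial thinning of the phylogeny's
  (Y_i | X_i ~ Bin(X_i, p)) and solves the aggregated score equation
  Σ (1 − 2p̂)^{X_i} = n − 2 Σ Z_i on [0, ½) by bracketed root finding.
* **Method 3 — Gamma-prior MAP** (`fit_gamma_map`): λ_i ~ Γ(α, β)
  integrated out in closed form; (α, β) fitted from the counts by
  intercept-only Negative-Binomial maximum likelihood (`fit_nb_prior`).

`crb_p` gives the Cramér–Rao lower bound on Var(p̂),

```
CRB(p) = [ 4 Σ_i λ_i² / (e^{4 λ_i p} − 1 + 4 p² λ_i) ]^{−1},
```

and `simulate` provides mtDNA-calibrated rate distributions
(Γ(0.23, 0.164) and a two-point mixture), direct Poisson-parity draws,
site-scaled K2P/TN93 sequence evolution with sparse transversions, and a
replicated benchmark harness with paired one-sided Wilcoxon tests.

Calibration: with a per-site per-year substitution rate μ = 1.57×10⁻⁸ and
a phylogeny accumulating 1.4 substitutions per site, the total tree
length is 1.4/μ ≈ 89.2 million years; TMRCA = ½(T₁ + T₂ + p_years) for
samples of ages T₁, T₂.

## Worked example

`examples/04_pipeline_tmrca.py` simulates a phylogeny summary and an
aligned pair at a known distance, then runs the full file-based workflow:

```
fixture: 16569 sites, 1001 phylogeny transversion sites, true p = 0.008
15562 sites survive transversion masking
estimated p = 0.00772 (0.77% +- 0.06%)
calibrated distance: 688,108 years (total tree length 89,171,975 years)
TMRCA (both samples modern): 344,054 years ago
```

The conditional estimator recovers the planted 0.8% distance within one
bootstrap SD, and half the calibrated distance dates the common ancestor
of two modern samples. `examples/02_estimate_distance.py` compares all
three estimators on one mtDNA-scale draw at p = 0.05:

```
Method 1 (joint MLE)         p_hat = 0.05158  (5.16% of tree length)
Method 2 (conditional)       p_hat = 0.04916  (4.92% of tree length)
Method 3 (Gamma MAP)         p_hat = 0.04910  (4.91% of tree length)
Cramer-Rao bound: sd(p_hat) >= 0.00211 for unbiased estimators
```

## Command line

A thin CLI wraps the same workflow; every command writes a JSON manifest
with its inputs, options and seed:

```bash
parityclock simulate  --n-sites 16569 --p 0.05 --seed 1 --out-dir fixture/
parityclock estimate  fixture/counts.tsv fixture/transversion_sites.txt \
                      fixture/pair.fasta fixture/pair.fasta --method conditional
parityclock benchmark --p 0.02 --p 0.1 --reps 500 --seed 1
parityclock crb       --lam 1.4 --n-sites 15629 --p 0.05
```

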