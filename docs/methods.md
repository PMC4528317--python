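# Methods

## The problem

Plant-breeding programs are structured into many biparental populations, so
the training set available for genomic prediction within any one population
is small. Pooling populations enlarges the training set but ignores genuine
between-population differences in marker effects (inconsistent marker–QTL
linkage phase, QTL-by-background interaction, population-specific alleles).
`poolwgr` implements *partial pooling*: a Bayesian multilevel whole-genome
regression in which population-specific marker effects are estimated but
shrunk toward shared overall effects, together with a BayesA baseline that is
fitted either per population (*no pooling*) or to the concatenated data
(*complete pooling*), and the replicated split protocol for comparing the
three approaches.

## Models

Phenotypes are line means, centered and scaled to unit variance on the
training set. Genotypes are reference-allele counts in {0, 1, 2}, centered by
twice the reference-allele frequency.

**Multilevel (partial pooling).** For line i of population j,

    y_ij ~ N(mu_ij, sigma_e^2),      mu_ij = beta_0 + sum_k z_ijk u_jk,
    u_jk ~ N(u_k, gamma_k^2),        u_k ~ N(0, sigma_k^2),
    sigma_k^2 ~ scaled-inv-chi^2(nu = 4.001, S^2),
    gamma_k ~ N(m, d^2)+             (left-truncated at zero),
    S^2, m, d ~ Uniform(0.001, 0.5),
    sigma_e ~ Uniform(0, 1),         beta_0 ~ N(0, 10^6).

A specific effect u_jk is estimated only where marker k is polymorphic in
population j; otherwise it is pinned to 0 and excluded from every
hierarchical conditional. `gamma_k^2` controls the shrinkage of u_jk toward
u_k; the mean of the truncated Normal N(m, d^2)+ — computed in closed form as
m + d·phi(m/d)/Phi(m/d) — is the "typical" deviation of specific from overall
effects and is reported per posterior draw as a population-divergence metric.

**BayesA (no/complete pooling).** The same likelihood without the population
index: u_k ~ N(0, sigma_k^2), sigma_k^2 ~ scaled-inv-chi^2(4.001, S^2). By
default S^2 carries a Gamma(1.1, 1.1) hyperprior with its conjugate Gamma
full conditional; a bounded-Uniform variant matching the multilevel model is
selectable (`s2_prior="uniform"`). The residual variance has the improper
scaled-inv-chi^2(−1, 0) prior, i.e. a flat prior on sigma_e, exploiting
conjugacy.

The "very large variance" of the intercept prior is fixed at 10^6 —
effectively flat on the standardized phenotype scale.

## Posterior computation

Both samplers are single-chain Metropolis-within-Gibbs schemes compiled with
numba; the scan order is fixed (parameter by parameter, markers in column
order) and each chain is bit-reproducible given its seed. Conjugate layers
use their Normal and scaled-inverse-chi-squared full conditionals; the
non-conjugate scalars of the multilevel model (gamma_k, m, d, S^2, sigma_e)
use univariate slice sampling (stepping-out, width 0.1, at most 50
expansions, shrinkage), clipped to their prior supports.

Three structural refinements keep the hierarchy well mixed; all leave the
target posterior unchanged:

1. **Collapsed gamma_k draws.** gamma_k is sampled from its conditional with
   the specific effects u_jk integrated out (the per-population marginal
   N(z u_k, sigma_e^2 I + gamma_k^2 z z') reduced to scalars by the matrix
   determinant lemma), after which the u_jk are redrawn from their full
   conditionals — a blocked draw of (gamma_k, u_·k). The naive centered
   update (gamma_k given current deviations) is self-referential: when the
   prior precision dominates, sampled deviations scale with gamma_k and the
   update reproduces its input, decoupling the divergence hierarchy from the
   data.
2. **Collapsed u_k draws.** u_k is likewise sampled with u_jk integrated out
   (Sherman–Morrison). Without this, data reach u_k only through u_jk, a
   channel whose bandwidth vanishes as gamma_k → 0, so the BayesA limit of
   the model (gamma pinned near zero) would mix at O(gamma^2) speed.
3. **Group scale move.** One Metropolis step per iteration proposes rescaling
   every deviation u_jk − u_k, every gamma_k, m and d by a common factor
   c = e^u, u uniform on (−0.3, 0.3), ten sub-proposals per sweep. The
   deviation and truncated-Normal priors are scale-equivariant, so the
   acceptance ratio is the data-likelihood change plus 2·log c from the
   Jacobian. This traverses the weakly identified overall scale of the
   divergence hierarchy, which coordinate-wise updates cross only by a slow
   random walk.

Residuals are maintained incrementally and refreshed from scratch every 1000
iterations to cancel float drift.

**Initialization** at interior points of all supports: beta_0 = 0, all
effects 0, sigma_k^2 = S^2 = 0.05, gamma_k = m = d = 0.05, sigma_e = 0.5.

**Chain presets.** `paper`: 1000 retained samples, burn-in 10 000, thinning
500 (the settings used for the reported full-scale analyses). `desk`: 500
retained, burn-in 2000, thinning 10 — the test-suite and interactive preset,
chosen so the full replicated simulation study runs on one CPU in minutes.
Under the `paper` preset on a small multi-population instance, every
monitored parameter reaches an effective sample size above 100 (most far
above), matching the convergence criterion used for the full-scale runs.

**Diagnostics.** `effective_sample_size` implements n / (1 + 2·sum rho_t)
with empirical autocorrelations accumulated by Geyer's
initial-positive-sequence rule and capped at n; it is cross-checked in the
test suite against `arviz.ess` and against the closed-form ESS of an AR(1)
process.

## Synthetic data

The paper-scale analyses behind this package used real maize data (the NAM
panel and a set of interconnected biparental DH populations). Those are
optional external inputs here (plain CSV/TSV import); the package instead
ships a generator that emulates their *structure*:

* a random multi-chromosome genetic map (default 10 chromosomes × 140 cM,
  285 markers, uniform positions);
* a panel of fully inbred founders (default 25 donors plus one common
  parent); per marker, a reference-allele frequency is drawn from
  [0.1, 0.5] ∪ [0.5, 0.9] and founder alleles are independent Bernoulli
  draws, with panel-monomorphic markers resampled so every marker is
  polymorphic across the panel;
* biparental families derived by simulated meiosis under the Haldane
  (no-interference) map function, r = (1 − e^(−2d/100))/2, with independent
  assortment across chromosomes: DH lines double a single F1 gamete; RIL
  lines follow single-seed descent for 6 selfing generations (residual
  heterozygotes coded 1).

Defaults mirror the NAM scale (25 families × 188 RILs). What the generator
does **not** emulate: real allele-frequency spectra and founder relatedness,
marker ascertainment, segregation distortion, crossover interference, and
genotyping error. Passing tests therefore demonstrate correct behaviour of
the methods under a clean biparental-structure model, not performance on any
real data set; absolute prediction accuracies on synthetic data are lower
than published full-scale values, and only orderings and qualitative
responses are asserted.

One structural consequence deserves emphasis: because founder alleles are
drawn independently, the linkage *phase* between a marker and a nearby QTL
is random in every cross. Even when the simulated QTL effects are identical
across populations (rSD = 0), the true *marker-level* population-specific
effects then still differ between families. On such data partial pooling
retains a small genuine accuracy edge over complete pooling at every rSD,
and the divergence metric has an elevated baseline with a correspondingly
compressed response to rSD. Real breeding panels, whose founders share
ancestry and whose marker phases are partially consistent across crosses,
show a stronger contrast between the pooling approaches at small versus
large rSD than this generator produces.

**Trait simulation.** 20 of the markers are drawn as QTL and removed from
the observed set. Overall additive effects a_q are standard normal;
population-specific effects a_jq ~ N(a_q, tau_q^2) with tau_q = rSD·|a_q|
(the published definition rSD = tau_q/a_q leaves the sign of a_q open; using
|a_q| keeps tau_q a valid scale and rSD a magnitude ratio). Genetic values
sum raw QTL allele counts times the line's population-specific effects
(centering would only shift each population's mean). Noise is i.i.d.
Gaussian with variance var(g)(1 − h²)/h², var(g) the empirical
(denominator-n) variance across all lines, so the realized across-population
heritability centers on the target (default 0.70). The mean within-family
heritability — var_j(g)/(var_j(g) + noise variance) averaged over
populations — falls as rSD grows, because diverging population effects
inflate the across-population genetic variance (and hence the calibrated
noise) faster than the within-family variance.

## Evaluation protocol

A split draws P populations into the training group Pi and, within each,
Np training lines (Lambda_p). Fractional Np is honoured exactly by giving
the accumulated remainder to one randomly chosen population (P = 20,
Np = 12.5 yields nineteen sets of 12 and one of 22, N = 250). A
fraction-based variant trains on round(fraction·size) lines of every
population, leaving no "new" populations. Within a replicate all approaches
see identical training rows.

Allele frequencies for centering are computed on exactly the training lines
each model sees — per population under no pooling, pooled otherwise — and
the same stored frequencies code the corresponding test lines, so training
and test genotypes share one scale. Phenotype standardization follows the
same scoping.

GEBVs are linear scores of centered test genotypes on posterior-mean marker
effects: population-specific effects u_jk for held-out lines of training
populations under partial pooling, overall effects u_k for new populations,
BayesA effects otherwise; the intercept is omitted as correlations are
shift-invariant. Accuracy is the within-population Pearson correlation of
GEBV with observed phenotypes (real data) or true genetic values
(simulations), averaged over Pi (r_Pi) and over the complement (r_Pi_bar;
not defined for no pooling). Correlations over fewer than 3 lines or with
zero variance are flagged, logged and excluded from the averages. Paired
two-sided t-tests compare approaches on per-replicate accuracies; a
zero-variance difference reports t = 0, p = 1 (identical) or p = 0
(constant shift).

## Design choices on genuinely open points

* **Frequency scope for centering** (not fixed by the published protocol):
  training-set scope, stored and reused for test lines, as above.
* **Markers monomorphic in an entire training subset**: their u_k is pinned
  to 0 and the marker is dropped from all hierarchical conditionals rather
  than rejected — random training subsets of biparental designs routinely
  lose polymorphism at some markers, and after training-scope centering such
  columns are identically zero anyway.
* **Standardization divisor**: population SD (denominator n); the choice is
  fixed only for bit-reproducibility.
* **S^2 hyperprior in BayesA**: Gamma(1.1, 1.1) with conjugate update as the
  default, the bounded-Uniform + slice variant as an option.
* **Residual heterozygotes in RILs** are kept and coded 1 (count scale), not
  recoded.

## Numerical notes and limitations

* Slice-sampler width 0.1 suits the standardized-phenotype scale of all
  bounded parameters; supports are enforced by interval clipping.
* The truncated-normal mean uses exp(log phi − log Phi) for stability; the
  upward shift underflows (correctly to m) once m/d is extreme.
* Desk-scale stochastic checks (orderings of pooling approaches across rSD,
  divergence-metric monotonicity) use 10 replicates and are inherently
  noisy; they assert orderings and signs, not published magnitudes.
* Single chain by design (as in the reported analyses); no R-hat, no
  multi-chain diagnostics.
* The multilevel sampler's cost grows with populations × polymorphic
  markers; hundreds of markers and tens of populations are comfortable on
  one CPU, genome-wide dense panels are out of scope.
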