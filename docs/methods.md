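# Methods

## The frequency recursion

The package models one generation of competition between an obligately
asexual (triploid, all-female) and a sexual (diploid, dioecious) lineage
sharing an environment.  With `q_t` the asexual frequency among parents and
the sexual per-capita birth rate a fraction `1/c` of the asexual one, the
asexual frequency among offspring is

    q_{t+1} = q_t W_asex / [q_t W_asex + (1 - q_t) W_asex / c]
            = c q_t / (1 + q_t (c - 1)).

`c` is the *net* cost of sex: it bundles the cost of producing sons with
every other fitness asymmetry between sexual and asexual females.  The
decomposition `c = r / s` separates the two — `1/s` is the cost of males
for a primary (brood) sex ratio `s`, and `r` is the ratio of surviving
offspring produced per asexual versus per sexual female.  Sons and
daughters are assumed equally costly, so `s` is read directly as the
proportion of daughters; the tertiary sex ratio among sexual adults is the
observable proxy used when the primary ratio is unknown.  The model has no
density dependence, no mixed mating and no ploidy-specific selection; it is
a single-generation selection model, which is also why the experimental
design it serves separates parents and offspring into discrete generations.

Frequencies are validated, never clamped: an out-of-range `q` raises, since
silent truncation would mask upstream count errors.  `fold_increase`
refuses `q_t = 0` (the ratio is undefined) but documents that its limit is
`c` — the familiar statement that a rare asexual mutant doubles per
generation under a two-fold cost.

## From raw counts to paired frequencies

A mesocosm-year contributes a dissection tally of ~150 parents (sex and
trematode-infection status), a flow-cytometry subsample of the dissected
uninfected *females*, and a flow subsample of unsexed offspring.  Infected
(castrated) snails are excluded throughout, because castration would
otherwise distort the relative birth rates being estimated.  Offspring
cannot be infected in this design (the trematode needs a bird host absent
from the tanks), so the `infected_offspring` column is bookkeeping only.

The parental asexual frequency is `q_t = T / (T + D + M̂)` with `T`/`D` the
triploid/diploid female flow counts and `M̂` the male count consistent with
a female subsample of that size, imputed from the mesocosm-wide dissection
sex ratio: `M̂ = (T + D) · males/females`.  `M̂` is kept fractional so the
ratio is exact; where an integer table is needed (the GLM stage's long
format) it is rounded half-to-even, and that table notes integer counts.
The offspring frequency needs no imputation: offspring were genotyped
unsexed, so `(k, n)` comes straight from the flow counts.

Replicates degenerate in either generation (an empty flow subsample) are
dropped with a warning rather than imputed — the replicate is the unit of
inference and there is no defensible way to restore a missing generation.
Drops and imputations are recorded in a JSON run log.

## Likelihood, candidate models, selection

Given a replicate's `q_t`, the offspring triploid count is modelled as

    k ~ BetaBinomial(n, α = q θ, β = (1 - q) θ),   q = q_{t+1}(q_t, c(year)),

the mean-parameterized beta-binomial: mean `q`, variance inflated by the
factor `1 + (n - 1)/(θ + 1)` relative to binomial; `θ → ∞` recovers
`Binomial(n, q)`.  The mapping to the conventional `(α, β)` shape
parameters is `α = qθ`, `β = (1-q)θ`.  The log-pmf is evaluated through
log-gamma functions and is stable to at least `n = 10^4`.  Predicted
frequencies of exactly 0 or 1 (possible when `q_t` sits on a boundary) are
truncated to `[1e-9, 1 - 1e-9]` so degenerate replicates stay in the
likelihood instead of being discarded.

Candidate models for `c`: fixed at 1 (`no_cost`), fixed at 2 (`two_fold`),
free (`mle`), and year-indexed (`mle_by_year`: a baseline `c0` for the
first year plus additive deviations `d_j`).  Parameter counts include the
shared dispersion, so k = 1, 1, 2 and 5 respectively for a four-year
design.  The year-indexed model's count deserves a note: a selection table
that lists the five symbols (θ, c0, d2, d3, d4) but a count of 4 is
inconsistent with its own AICc arithmetic at n = 24, which requires k = 5;
this package counts 5.

Optimization is Nelder-Mead on transformed coordinates — `log θ` and
`log c` (or `log c0`) for positivity, deviations untransformed with an
infinite penalty when `c0 + d_j ≤ 0` — with objective tolerance 1e-8 and
five jittered restarts by default (the surface is smooth and
low-dimensional; restarts are cheap insurance).  One numerical wrinkle:
when a dataset (often a bootstrap resample) is *under*dispersed relative to
binomial, the MLE of `θ` sits at infinity and the likelihood is flat along
the `log θ` ridge.  Fitting caps `θ` at 1e6 — indistinguishable from
binomial at subsamples of ~70 — with a quadratic nudge back to the cap, so
the simplex terminates there instead of drifting.  The cap applies to
fitting only; the pmf itself accepts any positive `θ`.

AICc uses `n` = the number of replicates (24 in the default design), not
the number of snails: replicates, not individuals, are the independent
units, and only this choice reproduces the selection-table arithmetic.
Models are ranked by AICc; Akaike weights
`w_i = exp(-Δ_i/2)/Σ exp(-Δ_j/2)` quantify relative support.

## Bootstrap procedures

Both uncertainty procedures case-resample the replicate pairs with
replacement.  `bootstrap_param_ci` returns percentile intervals (the
simplest defensible choice; BCa adds machinery the 24-replicate design
cannot really pay for).  `bootstrap_confidence_set` follows the ΔAIC
confidence-set recipe: refit all models per resample, record the focal
model's AICc minus the resample minimum, take the 95th percentile as the
limit, and keep every model whose actual-data ΔAICc is within it.

Resample fits start from the full-data estimates (single start) — the
resampled likelihood differs from the full-data one by the weighting of 24
terms, so the full-data optimum is an excellent start, and this keeps
coverage simulations tractable.  A master seed spawns one RNG substream per
resample, so results are independent of evaluation order.  Resamples whose
fit fails are dropped and counted; above 1% the result carries a warning.

## The logistic-regression stage

Independently of the recursion fit, the frequency change is tested with a
binomial-logit GLM of (triploid, diploid) counts on generation
(reference: parent), year (reference: first year) and optionally their
interaction.  IRLS is statsmodels'; the likelihood-ratio tests
(`D = deviance_reduced - deviance_full` against chi-squared), the
generation odds ratio, its profile-likelihood interval (deviance profiling
via an offset, root-found to 1e-8; Wald available as a fallback) and the
odds-ratio→fold-increase conversion

    fold = [odds₁/(1 + odds₁)] / p₀,   odds₁ = OR · p₀/(1 - p₀)

are implemented here.  On a single pooled 2×2 table the generation odds
ratio *is* the recursion's cost estimator — the two inferential routes
coincide algebraically, which the tests exercise.  The baseline `p₀`
defaults to the pooled parental proportion; a mean-of-replicate-means
variant is available, as the two differ when subsample sizes vary.  The
GLM assumes independence across replicate-generations; a
generalized-estimating-equation variant is deliberately out of scope (the
tidy layout keeps `mesocosm_id` so users can check exchangeability
externally).  No quasi-binomial dispersion correction is applied.

## The synthetic-data generator

The generator emulates the replicated mesocosm design well enough to
exercise every pipeline stage: latent parental frequencies drawn from a
truncated normal (mean 0.29, s.d. 0.08, truncated to (0.02, 0.98) — the
spread is a modelling choice, as only the mean is well constrained);
dissection of 150 parents with reproductive mode ~ Bernoulli(q_t), sex
among sexuals ~ Bernoulli(1 - s), and infection marks i.i.d. at rate
0.0982 independent of mode (an optional bias exists for robustness
experiments, off by default — the default generator tests exclusion
plumbing, not parasite selection); a parental female flow subsample drawn
*hypergeometrically* from the uninfected dissected females (target size
Poisson with mean 62, thinned binomially at the 6.01% exclusion rate); and
an offspring subsample (Poisson mean 70, thinned at 5.38%) whose triploid
count is beta-binomial around `q_{t+1}(q_t, c)` with dispersion θ = 40.
Defaults: 4 years × 6 mesocosms, true `c = 2`, `s = 0.5`.

A master integer seed spawns per-mesocosm substreams keyed by (year index,
mesocosm index), so identical configs are byte-identical and enlarging the
design leaves existing mesocosms unchanged.  The truth side-car records the
latent `q_t`, the expected `q_{t+1}` and the generating parameters;
inverting the recursion on those expectations returns the generating cost
exactly, which anchors the recovery tests.

What the generator does *not* emulate: clone-lineage structure and
multi-year eco-evolutionary dynamics, parasite-mediated selection,
size-selective sieving error between generations, or flow-cytometry gating
artefacts beyond i.i.d. exclusions.  Passing recovery tests therefore show
that the inference machinery is correct *under the stated sampling model*,
not that real mesocosm data satisfy that model.

## Problem sizes and reproducibility of the test suite

The simulation-based checks run 200 synthetic experiments for parameter
recovery and bootstrap coverage (B = 200 per experiment) and 100 for
model-selection sanity — sizes chosen to put Monte-Carlo error comfortably
inside the asserted bands while keeping the suite quick on a laptop.  All
stochastic tests fix seeds; hypothesis-based property tests are bounded
away from the extreme corners of parameter space where double-precision
cancellation (not the mathematics) dominates.

## Known limitations

* The recursion is deterministic between generations; drift within a
  mesocosm enters only through the beta-binomial observation model.
* `q_t` enters the likelihood as known, though it is itself an estimate
  (~62 genotyped females plus an imputed male count); the resulting
  errors-in-variables attenuation is small at these subsample sizes but
  not zero.
* The year-indexed model's deviations are additive on the cost scale;
  multiplicative (log-scale) deviations would be a reasonable alternative
  parameterization.
* Percentile bootstrap intervals at 24 replicates undercover slightly
  relative to nominal, as the coverage simulation documents (~91% for a
  nominal 95%).
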