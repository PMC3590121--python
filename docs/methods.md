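# Methods

## Model

For observation *i* (one branch or main stem, nested in tree *t(i)*,
nested in species *s(t)*), let **y**ᵢ be the vector of natural-log
traits (length in m, aboveground dry mass, stem dry mass, leaf dry
mass, all in kg) and *D*ᵢ the observed diameter in cm.

**Likelihood.**  The four traits are jointly multivariate normal around
tree-specific log-log power laws with a shared residual covariance:

```
yᵢ ~ MVN(μᵢ, Σ),       μᵢ,Y = α_{Y,t(i)} + b_{Y,t(i)} · log ρᵢ
```

Σ is a full 4×4 covariance; fitting the four relationships jointly lets
residual correlation among traits (a long branch for its diameter tends
to be a heavy one) inform every exponent.

**Measurement model.**  Field diameters carry multiplicative error.
The observed diameter is treated as a lognormal draw around a latent
true diameter ρᵢ (Berkson errors-in-variables):

```
Dᵢ ~ LogNormal(log ρᵢ, σ_ρ²),     log ρᵢ ~ Uniform(log 0.5, log 500)  [cm]
```

σ_ρ is fixed at 0.05 (≈5% relative error) for every observation and is
configurable.  Ignoring this term would attenuate exponents fitted on
noisy diameters; modelling it instead integrates over the latent
diameters.

**Hierarchy.**  Intercepts and exponents are partially pooled across
two levels, independently per trait and per parameter:

```
α_{Y,t} ~ N(a_{Y,s(t)}, σ²_{a,Y})      b_{Y,t} ~ N(b_{Y,s}, σ²_{b,Y})
a_{Y,s} ~ N(A_Y, τ²_{A,Y})             b_{Y,s} ~ N(B_Y, τ²_{B,Y})
```

The hierarchy is placed on α = log a (the fitting scale).  Tree-level
SDs are shared across species (one σ per trait and parameter), matching
a single tree-level variance component per relationship.  α and b are a
priori independent at every level.

**Priors.**  Uniform on bounded intervals: A_Y ∈ [−20, 20],
B_Y ∈ [−5, 5], all hierarchy SDs ∈ [0, 10].  Σ⁻¹ ~ Wishart(df = 5,
scale = I₄) — df = dimension + 1, the usual low-information choice.
All bounds are configurable (`ModelConfig`) and serialized into each
run's manifest.

## Sampler

Metropolis-within-Gibbs with conjugate blocks
(`treescale.sampler.run_mcmc`):

1. **Latent diameters** — vectorized random-walk Metropolis on log ρᵢ
   (the full conditionals factor across observations).
2. **Tree parameters** — each tree's (α, b) across the four traits is
   one 8-dimensional conjugate normal: likelihood precision
   Σ⁻¹ ⊗ XᵗX plus the diagonal hierarchy precision.
3. **Species and global means** — scalar conjugate normals; the global
   draw is a truncated normal respecting its uniform support.
4. **Hierarchy SDs** — random-walk Metropolis on log σ with the
   proposal Jacobian, rejecting outside (0, 10].
5. **Residual precision** — conjugate draw
   Σ⁻¹ ~ Wishart(df₀ + n, (S₀⁻¹ + RᵗR)⁻¹) via Bartlett decomposition.

Random-walk scales adapt toward ~30% acceptance in windows of 100
iterations during burn-in only and are frozen afterwards, so the
post-burn-in kernel is a fixed, valid MCMC kernel.  Chains are seeded
from a `SeedSequence` spawn of the sampler seed; identical seeds give
bit-identical draws.

Initialization: per-tree ordinary least squares on the log data
(falling back to species, then global pools for trees with fewer than
three observations or no diameter spread); Σ from the pooled OLS
residual covariance; latents at observed log D; a small seeded jitter
(SD 0.05) overdisperses the chains for the scale-reduction diagnostic.

Protocols: the default `SamplerConfig()` is the full field protocol
(3 chains × 1,000,000 iterations, burn-in 200,000, thin 10).
`desk_scale()` (3 × 6,000, burn-in 2,000, thin 2) is used for the test
suite and examples; on the 286-observation design it mixes well
(acceptance ~30%, R-hat < 1.01 on global parameters) and runs in about
ten seconds.

## Diagnostics

`rhat` is the classical potential scale reduction
√(((K−1)/K·W + B/K)/W).  The pipeline's convergence gate requires
R-hat ≤ 1.1 on the eight global parameters.

`heidelberger_welch` performs the Cramér–von Mises stationarity test on
the Brownian bridge of the chain's cumulative sums, iteratively
discarding the first 10%…50%, followed by the halfwidth test
(1.96·√(S(0)/n) against 10% of the mean's magnitude).  The spectral
density at frequency zero is estimated by **batch means** (20 batches)
rather than an AR fit: an autoregression absorbs a deterministic trend
into a near-unit root, inflating the denominator until clearly trending
chains pass as stationary, while batch means keeps the statistic
sensitive to trends and calibrated on stationary chains.  The AR
estimator remains available as `spectrum0_ar`.

## Posterior predictive checks

One replicate dataset per retained draw (subsampled evenly to
`n_replicates`), simulated at the draw's latent diameters.  Per trait:

* `T_mean` — the trait's column mean; `P_B_mean` is the fraction of
  draws with replicate mean ≥ observed mean (ties count as extreme).
* `T_fit` — Σᵢ (yᵢ − μᵢ(θ))², compared between replicate and observed
  data at the same draw; `P_B_fit` defined the same way.
* `r²` — squared Pearson correlation between each observed log trait
  and its posterior-mean prediction; undefined (reported missing, with
  a warning) for a zero-variance trait.

Statistics are per trait, matching the per-trait structure of the
model-fit reporting.

## Theoretical-model scoring

Predictions are exact rationals (MST: 2/3, 8/3, 8/3, 2; GEOM: 1, 3, 3,
2; STRESS: 1/2, 5/2, undefined, undefined) compared at full precision
against the floating CI bounds.  For each trait the 95% equal-tailed
intervals of every tree, every species and the global level are scored
(29 intervals per trait under the study design), inclusion percentages
use only cells where a theory makes a prediction, and best-model ties
are reported as a set.  Species contrasts are posterior probabilities
P(b_a − b_b > 0) from pooled draws; by construction
P(a,b) + P(b,a) = 1 for continuous draws.

## Synthetic data

The generator runs the model forward and therefore shares its exact
structure: hierarchy draws per Eqs. above, latent log diameters uniform
over the log diameter range, lognormal measurement error, MVN traits.

Study-design defaults (`GeneratorConfig()`):

* 3 species; 10/5/10 trees; 103/30/128 non-stem branches split evenly
  across trees plus one main stem each — 286 observations.
* True exponents B = (0.75, 2.65, 2.70, 2.00) for (length, AG mass,
  stem mass, leaf mass) — inside the credible ranges reported for
  savanna trees.  Intercepts (−0.12, −3.04, −3.22, −4.20 on the log
  scale; diameter cm, length m, dry mass kg) put a 10 cm stem at ~5 m
  of branch, ~20 kg stem and ~1.5 kg leaf — a leaf fraction near 7%,
  typical of savanna trees, which also makes the emergent exponent of
  stem + leaf mass consistent with the configured aboveground exponent.
* Hierarchy SDs: tree level σ_a = 0.08, σ_b = 0.04 (consistent with the
  very small tree-level variance components reported for such data);
  species level τ_A = 0.15, τ_B = 0.08 (species exponents broadly
  overlapping, spread ≈ 0.1).
* Residual SDs (0.27, 0.58, 0.54, 0.73) with correlation 0.5 among the
  mass traits and 0.2 with length, chosen so log-log fit quality lands
  in the realistic r² ≈ 0.85–0.95 band.
* σ_ρ = 0.05; latent diameters uniform on the log scale over
  [2.2, 40] cm.  Observed diameters are redrawn when measurement noise
  would push them below the 2 cm field threshold, mirroring a protocol
  that only records branches at or above 2 cm
  (`min_observed_diameter`, settable to `None`).

**Two modes.**  In `model-exact` mode trait columns are already
downstream-aggregated quantities and the exact simulated log-trait
matrix is kept on `TrueParameters.log_traits`; `to_observation_table`
builds the correctly specified fitting input from it.  In `raw-field`
mode each subtree's aggregated dry mass is redistributed into
per-segment wet masses (segment = own aggregate − daughters'
aggregates), so preprocessing must reproduce the aggregates; a negative
segment mass triggers a resampling of the offending daughter's topology
position (reparenting it to a thicker ancestor), with a full per-tree
redraw as fallback, both counted in the generator metadata.

**A structural tension worth knowing about.**  The likelihood treats
all four log traits as jointly MVN, but aboveground mass is by field
construction the sum of stem and leaf mass.  Serialized branch records
carry stem and leaf aggregates, so tables rebuilt through preprocessing
have AG mass = stem + leaf — an emergent, slightly diameter-dependent
exponent rather than an exact power law.  With the default intercepts
the emergent exponent matches the configured 2.65 closely.  Recovery
studies use the model-exact table, where all four traits follow the
likelihood exactly.

**What the generator does not emulate:** empirical diameter
distributions (the latent uniform-in-log choice spreads leverage evenly
but is a modelling convenience — field diameter distributions are
unreported for this design), parent–daughter correlation of residuals
beyond the tree level, bark/height distinctions, and any
fire/browsing/competition processes.  Passing tests therefore show the
machinery is correct under the model's own assumptions, not that the
model is adequate for any particular field dataset.

## Numerical choices and edge cases

* Natural logarithms throughout (only intercepts depend on the base).
* Observations with any non-positive trait after aggregation are
  dropped whole, with a logged count — the log-scale likelihood has no
  support for them.
* The ≥ 2 cm diameter filter is applied after aggregation, so a small
  branch's mass still counts toward its ancestors.
* Zero hierarchy SD: −∞ on any mismatch, a degenerate point mass (zero
  contribution) on exact equality.
* Non-SPD Σ: likelihood and posterior return −∞ rather than raising.
* Quantiles are linearly interpolated order statistics of the pooled
  post-burn-in draws.
* `P_B` uses ≥ so ties count as extreme.
* Best-model ties are reported, never broken.

## Problem sizes used in the tests

The test suite fits the 286-observation study design with the
desk-scale protocol (~10 s per fit), runs 20 seeded recovery replicates
for credible-interval coverage, and checks the conjugate Wishart block
at 10,000 residual rows; the full suite completes in roughly three
minutes on one core.

## Known limitations

* The sampler is single-machine, pure NumPy; no gradient-based
  alternatives are provided.
* The measurement SD σ_ρ is fixed, not estimated; its value encodes
  external calibration information.
* With only three species, the global level is weakly identified and
  its credible intervals are wide and prior-sensitive (uniform SD
  priors have heavy right tails at this group count) — visible in the
  worked example's global length interval.
* Environmental covariates (rainfall, fire frequency, cover) are out of
  scope by design.
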