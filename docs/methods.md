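# Methods

## Model

`opennmix` fits the open N-mixture (state-space) model for multi-site
count time series with one seasonal total per site and year:

    N_{i,first} ~ Poisson(Lambda_i)
    N_{i,t}     ~ Poisson(lambda_t * N_{i,t-1})
    y_{i,t}     ~ Binomial(N_{i,t}, p_t)

`N_{i,t}` is the latent number of adults at site `i` in year `t`,
`y_{i,t}` the observed seasonal total, `lambda_t` the multiplicative
population growth rate and `p_t` the per-individual detection
probability.  Growth and detection are constant within *strata* —
calendar periods (decades in the national analyses), optionally crossed
with regions — and the transition into year `t` uses the stratum
containing `t` (growth realised "into" a year belongs to that year's
stratum).  By default one national growth rate is shared by all sites
within a period; `by_region` switches both growth and detection to
region x period strata (the regional variant of the UK analysis).  Latent dynamics advance through every calendar year between a
site's first and last observation; unsurveyed years simply emit nothing.
Sites are independent given the parameters.

Assumptions worth stating plainly: no immigration or recruitment term
beyond the Poisson growth kernel, no environmental (year-level shared)
stochasticity, no observer covariates, and detection acting as a single
binomial thinning of the seasonal total.  A count of 0 is a valid
observation; a missing year is a gap, never a zero.

## Exact likelihood

The marginal likelihood of a site's series sums over all latent
trajectories.  It is computed by a forward pass over the truncated state
space `{0..K_i}`:

* **Truncation rule.** `K_i = max(ceil(3 * max_count_i / p_floor),
  max_count_i + 50)` with `p_floor = 0.25` by default: the largest count
  divided by a pessimistic detection bounds plausible abundance, times a
  safety factor of 3.  Doubling every `K_i` changes the log likelihood
  by far less than 1e-6 at this rule (tested).
* **Truncation convention.** Transition rows are raw Poisson pmfs with
  the mass beyond `K` dropped, so the likelihood is that of the data
  jointly with abundance never exceeding `K`; it is monotone
  non-decreasing in `K`.  The alternative convention that folds the tail
  into state `K` (rows sum to one) is available
  (`TruncationConfig(fold_tail=True)`) but is *not* the default: the
  folded bound state is self-absorbing whenever `lambda >= 1` — staying
  at `K` costs ~log(0.5) per year versus ~log(1/sqrt(2*pi*lambda*N)) for
  a genuine transition — and under diffuse priors this manufactures a
  spurious posterior mode at (N = K, small p).  We verified this by
  comparing brute-force grid posteriors with and without folding on tiny
  datasets.
* **Banded evaluation.** Each Poisson row is evaluated only on
  `mean ± 6.5 sd + 20` states, pmfs by a two-term recursion, and the
  filtered vector keeps an active window above 1e-13 of its maximum.
  Cost is therefore proportional to the posterior spread of `N`, not to
  `K`; counts up to 12 000 with `p >= 0.1` evaluate in well under a
  second.  Agreement with explicit path enumeration on small instances
  is ~1e-12; likelihoods below the pruning floor (astronomically
  mis-specified parameter/data combinations) return -1e300.

A brute-force enumerator over all `(K+1)^S` trajectories implements the
identical conventions and serves as the independent oracle in the tests.

One consequence of raw truncation worth knowing: the truncated model's
prior over trajectories includes the probability of never exceeding `K`,
so "prior recovery" checks (no-data runs returning the uniform priors)
require `K` far above any latent state reachable under the prior — with
the default data-driven rule this always holds, but hand-set small `K`
with a large growth bound tilts the no-data posterior of `lambda`
downward, correctly reflecting the truncated model itself.

## Maximum likelihood

`fit_mle` maximises the marginal likelihood over stratum growth rates
(log scale) and detection (logit scale), profiling each site's
`Lambda_i` out with a bounded scalar search on `log Lambda in
[log 1e-3, log 2K_i]`.  The outer problem is solved by bounded
Nelder-Mead from three dispersed starts (growth 0.8/1.0/1.2, detection
0.3/0.5/0.7) because the inner profiling makes finite-difference
gradients unreliable and the likelihood can be multimodal at low
detection.  Detection can be pinned (`fix_p=1.0`) for perfect-detection
checks, where the likelihood collapses to products of Poisson pmfs and
the two-year MLE equals the ratio statistic `sum(y_t)/sum(y_{t-1})`.

## Bayesian fitting

Priors follow the replication protocol and are deliberately diffuse and
uniform: `p ~ U(0,1)` per stratum, `lambda ~ U(0, 5)` per stratum, and
`Lambda_i ~ U(0, 2 K_i)` (all bounds configurable).  A variant with a
discrete-uniform prior directly on `N_{i,first}`
(`init_prior="discrete_uniform"`) is provided because the protocol's
wording supports either reading; both behave alike in our checks.

One sampler iteration is:

1. **Latent refresh** — exact forward-filtering backward-sampling (FFBS)
   of every site's trajectory on `{0..K_i}` given current parameters.
2. **Conjugate draws** — `p_s | N, y ~ Beta(1 + sum y, 1 + sum(N - y))`
   over the stratum's observed site-years; `lambda_s | N ~ Gamma(1 + sum
   N_t, sum N_{t-1})` truncated to the prior interval (transitions out of
   `N = 0` carry no information and drop out); `Lambda_i | N_first ~
   Gamma(1 + N_first, 1)` truncated.  These conditionals are exact, so no
   Metropolis step is needed for them.
3. **Marginal detection refresh** — every few iterations (each iteration
   during burn-in, every 5th after; 2 proposals per refresh), all
   detection strata are proposed jointly on the logit scale while every
   `Lambda_i` is deterministically rescaled by its first-year stratum's
   `p/p'`, and the proposal is accepted against the *marginal* likelihood
   (latents integrated out by the forward pass) with the appropriate
   Jacobian terms.  This move exists because detection and abundance form
   a ridge — lowering `p` and raising `N` and `Lambda` leaves expected
   counts unchanged — which conditional updates cross only by slow
   diffusion.  Step sizes adapt toward ~25% acceptance during burn-in and
   are frozen afterwards.  Growth rates need no marginal refresh: their
   Gamma conditionals depend on abundance ratios, not the abundance
   scale.

Chains start overdispersed (growth 0.5/1.0/1.5, detection 0.2/0.5/0.8,
`Lambda_i = max_count/p_start`) so the Gelman-Rubin statistic is
meaningful.  The default protocol is three chains of 10 000 iterations,
2 000 burn-in, thinning one-in-ten.  All randomness derives from the
config seed with one substream per chain; identical data, config and
seed reproduce bit-identical retained draws.

The sampler was validated against brute-force grid posteriors (all
`Lambda_i` integrated numerically from the exact likelihood) on two- and
four-site datasets: posterior means and 95% intervals agree to ~0.003.

### Identifiability of detection, and a deliberate red flag

With a single seasonal count per site-year, detection is identified only
through the serial-variance structure of the counts (given the previous
latent state, `y_t` is exactly Poisson(`p * lambda * N_{t-1}`), so `p`
enters only via how well `y_{t-1}` proxies `N_{t-1}`).  That information
is weak — a few hundredths of a nat per transition — while the flat
per-site prior on `Lambda_i` contributes a volume factor per site (the
width of the `Lambda` slab consistent with the data grows like `1/p`).
The net effect, verified by numerically integrating `Lambda_i` out of
the exact likelihood on a grid, is that the *exact* posterior of `p`
peaks ~0.1-0.25 below the profile-likelihood peak (which sits at the
truth) at volunteer-count scales, and the displacement does not shrink
with more sites, because both terms grow with the site count.  Posterior
detection estimates under this protocol should therefore be read as
lower bounds, a structural caveat the original analyses also noted.
Growth rates are unaffected — their conditionals are invariant to the
overall abundance scale — and growth-rate recovery on synthetic truth is
accurate to well under 0.02 with calibrated interval coverage.  The
package's acceptance suite asserts the detection-recovery tolerance
anyway and lets it fail, as an honest record of this model property.

## Synthetic data

The generator draws from the exact model above, emulating the volunteer
road-crossing ("toad patrol") study design.  Defaults: 140 sites; a
four-decade scheme (1973-2012) with decade growth (1.081, 0.977, 0.982,
0.980) and detection (0.390, 0.358, 0.420, 0.443) — decade values
typical of the Swiss common-toad series; site initial-abundance means
log-uniform on [50, 8000] animals (most populations small, a few in the
thousands); series spans drawn as `5 + Poisson(mu)` with `mu` set so the
mean number of *observed* years hits the 14-year target after interior
years go unsurveyed with probability 0.1 (first and last years are
always observed); start years uniform over the feasible window.  Per-site
RNG substreams make generation order-independent and reproducible.

A `recovery_scenario` variant (three decades 1985-2014, growth 1.05 /
0.98 / 0.97, detection 0.3 / 0.4 / 0.5, `Lambda` log-uniform on
[20, 200]) keeps the state space small enough for exact validation and
is the benchmark for parameter-recovery checks.

What the generator does *not* emulate: volunteer attrition after
declines (series ending is independent of abundance), within-season
nightly counts, environmental stochasticity, observer turnover, or
road-mortality feedback.  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model, not robustness
to these real-data features.

## Diagnostics and reporting

* `gelman_rubin` implements the classic between/within-chain form: with
  `m` chains of `n` draws, `W` the mean within-chain variance, `B/n` the
  variance of chain means, `R-hat = sqrt(((n-1)/n W + B/n)/W)`; flagging
  threshold 1.1.  A rank-normalised split variant is available via
  ArviZ (`method="rank"`).
* `posterior_summary` reports pooled means and equal-tailed credible
  intervals (percentile rule; mass 0 degenerates to the median), with
  effective sample sizes from ArviZ.
* `project_decline(lambda, h) = 100 (1 - lambda^h)`; the red-list
  criterion A2 mapping uses inclusive cut-offs 30/50/80% (a decline
  exactly at a threshold takes the more threatened category).  Decline
  projections are reported at the posterior mean and at both interval
  endpoints rather than propagating the full posterior; the draws are
  available when full propagation is wanted.
* An annual growth rate of 0.96 compounds to a 33.5% loss over ten
  years, which crosses the 30% "vulnerable" threshold — the arithmetic
  behind the headline conservation claim.

## Problem sizes in the test and acceptance runs

Exactness checks run on hundreds of randomly drawn tiny instances
(series of up to 3 observed years, `K <= 6`) where full path enumeration
is feasible.  Bayesian recovery checks run the reduced protocol (3
chains x 2000 iterations, 500 burn-in, thin 10) on a 40-site benchmark
dataset, and interval-coverage checks use 20 replicate 8-site datasets
with 2 chains x 1200 iterations (500 burn-in) each — small datasets with
a well-converged protocol, because under-converged chains would narrow
the intervals and measure compute, not calibration; maximum-likelihood
recovery uses 60-100 sites at perfect detection.  These sizes were
chosen so the whole suite completes on a single CPU while leaving the
Monte-Carlo error of each check well below its assertion tolerance; the
same computations scale unchanged to the full 130-160-site national
datasets with the long protocol.

## Known limitations

* Detection estimates are structurally biased low under the diffuse
  uniform priors (see above); comparisons of `p` against published
  values should expect agreement in pattern, not level.
* No environmental stochasticity: year effects shared across sites are
  absorbed into the decade growth rates; allowing them would likely
  raise detection estimates.
* The truncated likelihood drops trajectories above `K_i`; with the
  default rule the neglected mass is far below numerical tolerance, but
  pathological parameter combinations (growth near the prior bound for
  long horizons) are clipped rather than represented.
* The MLE profiles initial abundance rather than maximising jointly;
  profile confidence statements are not implemented.
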