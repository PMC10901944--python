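# Methods

## Model

`scsm` fits a Bayesian shared component spatial model (SCSM) to two count
outcomes observed on the same set of small areas — the motivating case is
offender counts and offense counts per census dissemination area (DA). For
area *i* and outcome *k* ∈ {1, 2}:

    O_ik ~ Poisson(e_ik · r_ik)
    log r_i1 = α₁ + δ θ_i + s_i1 + u_i1
    log r_i2 = α₂ + (1/δ) θ_i + s_i2 + u_i2

* `e_ik` — expected count from indirect standardization (region-wide
  reference rates, optionally stratified by sex × age group, applied to the
  area's population). By construction Σᵢ e_ik = Σᵢ O_ik.
* `θ` — latent spatial field shared by both outcomes; a surrogate for
  unmeasured risk factors common to them. It enters the two outcomes with
  reciprocal scalings δ and 1/δ (δ > 0), which aids identifiability and lets
  the two outcomes load on the shared surface with different gradients.
* `s_k` — outcome-specific spatially structured field; `u_k` —
  outcome-specific unstructured (iid normal) effect. Together these are the
  usual BYM convolution pair.

`θ`, `s₁`, `s₂` carry intrinsic CAR (ICAR) priors on the contiguity graph:
conditionally, each area's value is normal around the mean of its
neighbours with variance (1/τ)/mᵢ. The joint kernel used everywhere is the
pairwise-difference form

    ((n − c)/2)·log τ − (τ/2)·Σ_{i~j} (x_i − x_j)²

with `c` the number of connected components — `n − c` is the rank of the
graph Laplacian and the correct exponent for the improper density, also
used in the conjugate precision updates.

Priors: Gamma(0.1, 0.1) on the three structured precisions, Gamma(0.01,
0.01) on the two unstructured precisions, flat-normal intercepts realized as
N(0, 10⁶), and log δ ~ N(0, 1/5.9). The 5.9 comes from a calibration
exposed as `precision_for_ratio_bounds`: the ratio of the two risk
gradients is δ², so requiring it to lie in [1/5, 5] with 95% probability
gives precision (z₀.₉₇₅ / (log 5 / 2))² ≈ 5.93 → 5.9. A sensitivity
alternative (uniform priors on the standard deviations, U(0,10) structured
and U(0,100) unstructured) is available via `PriorSpec.sensitivity()`; the
sampler then updates those precisions by Metropolis on log τ instead of
conjugate Gibbs.

### Identifiability conventions

The ICAR prior is improper (invariant to a constant shift per component),
so with free intercepts the model is unidentified. We enforce sum-to-zero
on `θ`, `s₁`, `s₂` within every connected component by recentring after
each sweep, absorbing the subtracted (area-weighted global) mean into the
corresponding intercept — on a connected graph this leaves the likelihood
exactly unchanged; with several components the residual per-component
offsets are projected out without compensation (exact only up to the
between-component mean spread; lattices used for validation are connected).
Islands (areas with no neighbours) have no conditional distribution under
the ICAR prior; their structured effects are pinned at zero and they carry
risk only through `u_k` and the intercepts.

Some presentations of this model distinguish a conditioning mean from the
Poisson mean; here the Poisson mean is always λ_ik = e_ik·r_ik.

## Sampler

Metropolis-within-Gibbs, re-implemented from scratch (no external MCMC
engine):

* **Single-site random-walk Metropolis** for every coordinate of `θ`,
  `s₁`, `s₂`, `u₁`, `u₂` and for `α₁`, `α₂`, `log δ`, in a fixed scan
  order. The inner loop is a compiled (numba) kernel; all random variates
  come from a per-chain `numpy.random.Generator`, so runs are exactly
  reproducible from the seed.
* **Conjugate Gibbs** draws for the five precisions: ICAR fields give
  Gamma(a + (n−c)/2, b + ½Σ_{i~j}(x_i−x_j)²), iid fields
  Gamma(a + n/2, b + ½Σx²).
* **Likelihood-invariant mixing moves.** The decomposition of risk into
  shared vs specific (and structured vs unstructured) components is only
  weakly identified, and plain single-site updates traverse that ridge very
  slowly (it shows up as chains that agree on `δθ + s₁ + u₁` but disagree
  on the split). Three extra Metropolis moves propose transfers that leave
  both linear predictors — hence the likelihood — unchanged, so the accept
  ratio involves priors only:
  1. per site: θᵢ += t, s₁ᵢ −= δt, s₂ᵢ −= t/δ;
  2. per site and outcome: s_kᵢ += t, u_kᵢ −= t;
  3. globally: log δ += ε, θ scaled by e^(−ε), s₂ sheared by
     (θ/δ)(1 − e^(−2ε)); this deterministic map needs the Jacobian term
     e^(−ε(n−c)) for the θ scaling restricted to the sum-to-zero subspace.
  Each is a valid Metropolis–Hastings move with the posterior invariant;
  they change mixing, not the target.
* **Adaptation**: proposal scales adapt toward 0.44 acceptance in batches
  of 50 sweeps during burn-in only; the retained-phase kernel is fixed, so
  detailed balance holds for all stored draws.
* **Initialization**: each chain starts from over-dispersed values (normal
  perturbations of fields, intercepts and log-precisions, spread increasing
  with chain index), then recentred onto the constraint surface.
* **Diagnostics**: Brooks–Gelman–Rubin potential scale reduction factor per
  scalar parameter over ≥ 2 chains (flag threshold 1.1 — conventional), and
  a batch-means Monte Carlo standard error check per parameter against the
  rule MCSE < 5% of the posterior SD.

Default chain settings mirror the reference protocol (2 chains, 20,000
burn-in iterations, 10,000 retained iterations thinned by 100 → 100 stored
draws per chain); burn-in and retained counts are raw sweep counts, with
thinning applied on top, so both numbers are explicit rather than guessed.

## Posterior outputs

All functionals are computed per retained draw and then summarized —
never by plugging posterior means into nonlinear formulas — to avoid
Jensen-gap bias:

* **Risk surfaces**: posterior means and 95% intervals of the shared risk
  exp(θᵢ), the specific risks exp(s_ik + u_ik) and the combined risks r_ik.
* **Hotspots**: exceedance probabilities Pr(exp(θᵢ) > 1 | data) and
  Pr(exp(s_ik+u_ik) > 1 | data) estimated as the fraction of draws above 1,
  then binned into probability classes (default interior edges 0.2, 0.4,
  0.6, 0.8, 0.96; bins half-open [lo, hi) with the top bin closed, so the
  top class is [0.96, 1]). The report highlights ≥ 0.8 and ≥ 0.96 classes;
  both are configurable because no single cutoff is canonical.
* **Variance decomposition**: per draw, the across-area sample variances
  (ddof = 1) of δθ, s₁, u₁ (outcome 1) and (1/δ)θ, s₂, u₂ (outcome 2);
  the fraction shared is Var(scaled θ) over the total, and the three
  fractions sum to one per draw by construction. Var(s_k + u_k) is reported
  alongside Var(s_k) + Var(u_k) since the two differ in finite samples.
* **Scaling summary**: δ and 1/δ summarized from their own draws (the mean
  of 1/δ is not 1/mean δ); the risk-gradient ratio reported both as
  mean(δ)/mean(1/δ) — the headline arithmetic style — and as the posterior
  mean of the per-draw δ².

## Synthetic data and what it does (not) show

Real small-area offender/offense data are access-restricted, so all
validation is on data simulated from the model itself. The generator uses:

* a queen-contiguity lattice in place of DA polygons (same adjacency
  semantics, no geometry files needed); default 15×15, up to ~33×34 ≈ 1,122
  areas to match the scale of a realistic regional DA layer;
* populations uniform on {400,…,800} (the DA design population) and
  expected counts proportional to population with a configurable mean of 8
  events per area per outcome, which puts outcome-1 counts in the
  observed 0–35 range;
* exact constrained-ICAR draws for θ, s₁, s₂ via the eigendecomposition of
  the graph Laplacian per component (covariance = pseudoinverse / τ, zero
  sum per component by construction), iid normals for u₁, u₂;
* default truth δ = 1.17 and precisions (τ_θ, τ_s, τ_u) = (1.25, (0.9,
  1.7), (50, 2.8)). On lattices of the tested sizes the ICAR marginal
  variance is ≈ 0.29/τ, so these defaults realize a realistic fitted
  variance regime: Var(δθ) ≈ Var(s₁) ≈ 0.32 with Var(u₁) ≈ 0.02 for
  outcome 1, and Var(θ/δ) ≈ Var(s₂) ≈ 0.17 with a dominant Var(u₂) ≈ 0.36
  for outcome 2.

The generator reproduces the model's dependence structure but none of the
artefacts of real crime data: geocoding error, under-reporting, offender
mobility, irregular polygon geometry, or heterogeneous DA populations
beyond the uniform range. Passing recovery tests therefore demonstrates
that the implementation estimates what the model defines, not that the
model is adequate for any particular police dataset.

"True" variance fractions are defined on the realized (finite-sample)
fields, not on prior variances — that is the estimand the empirical
variance statistic targets — and are computed by an implementation
deliberately independent of the posterior-analysis code path.

## Recovery study design

The scaled-down study behind the recovery checks: 50 replicates on a 12×12
lattice, truth δ = 1.5 with τ_θ = 2.0 (so the variance regime above
still holds at that δ), two chains of 8,000 burn-in + 8,000 retained sweeps
thinned by 40 (400 pooled draws) — chain lengths chosen so that the BGR
statistic is comfortably below 1.1 on datasets of this size. Scored
quantities:

* coverage of the 95% credible interval for δ and for the per-outcome
  fraction shared, against the realized truth;
* posterior-mean bias for the same quantities;
* ordering recovery of the three variance fractions. Because the regime of
  interest sets two generative variances exactly equal, truth pairs whose
  realized fractions differ by less than 0.1 are treated as ties: an
  estimator cannot be asked to call a coin flip. A replicate counts as
  recovered when, for both outcomes, every decisively ordered truth pair is
  reproduced strictly by the posterior-mean fractions.

## Numerical choices

* Boundary-lying points in point-in-polygon counting use a closed-boundary
  (covers) test; ties on shared boundaries go to the lowest area id —
  deterministic and reportable.
* Queen contiguity is the default (a single shared boundary point makes a
  neighbour pair); rook is available by configuration.
* Areas with zero population (hence zero expected count) cannot enter the
  Poisson likelihood on the log scale and are excluded with a logged,
  machine-greppable warning listing their ids.
* Degenerate diagnostics: a constant chain has zero posterior SD and passes
  the MCSE rule automatically with a warning; identical chains give a BGR
  statistic of 1 (up to the (n−1)/n finite-length factor).
* Long-format CSV export holds every scalar draw; the `.npz` cache is the
  lossless binary round-trip used by `summarize`.

## Known limitations

* The shared/specific decomposition is weakly identified at realistic
  small-area event rates: credible intervals for the variance fractions are
  wide and calibrated (the recovery study scores their coverage), but
  posterior-mean fractions shrink toward the prior, and the point ordering
  of near-by fractions should not be over-interpreted. The scaling
  parameter δ shrinks toward 1 under its calibrated prior for the same
  reason.
* Shapefile input is not supported; polygon layers must be GeoJSON.
* No CRS handling: events and polygons must already share a coordinate
  system.
* With several connected components, recentring is exact for the constraint
  but the intercept absorption is exact only for the global mean; fits on
  heavily fragmented graphs should be checked with the BGR diagnostics.
* The sampler is single-threaded by design (reproducibility over speed);
  the ~1,100-area study scale fits in minutes, but much larger lattices
  would benefit from a blocked sampler this package does not implement.
* No covariate (fixed-effect) terms, no spatio-temporal extension, and no
  multivariate-CAR alternative.
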